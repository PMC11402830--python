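"""Rank-normalised structural damage (ΔΔG_rank) and biallelic genotype scoring.

The scoring scheme converts predicted folding free-energy changes (ΔΔG,
kcal/mol) for every possible missense variant into a rank-normalised score
on [0, 1] per structural context (full dimer vs isolated monomer), then
scores a genotype as the mean of its two allele scores, with wild type = 0
and truncating (null) alleles = 1. Ranking uses |ΔΔG| by default, so
strongly stabilising substitutions also count as damaging; a signed-ranking
switch is provided. Dimer and monomer contexts are ranked independently,
each over its own full set of possible missense variants.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .variants import Allele, AlleleKind, Consequence, Genotype, Subject

Context = Literal["dimer", "monomer"]


@dataclass
class DdgTable:
    """Per-substitution ΔΔG values (kcal/mol) for one structural context."""

    context: Context
    entries: dict[tuple[int, str], float]
    covered_positions: frozenset[int]
    ref_aa: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.covered_positions = frozenset(self.covered_positions)
        for (pos, alt), _ in self.entries.items():
            if pos not in self.covered_positions:
                raise ValueError(f"entry at position {pos} outside covered_positions")
            if self.ref_aa.get(pos) == alt:
                raise ValueError(
                    f"self-substitution entry {alt}{pos}{alt} is not a missense variant"
                )

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class RankScoreTable:
    """ΔΔG_rank (or predictor-rank) scores in [0, 1] for one context."""

    context: str
    scores: dict[tuple[int, str], float]
    covered_positions: frozenset[int]

    def __post_init__(self) -> None:
        vals = np.fromiter(self.scores.values(), dtype=float, count=len(self.scores))
        if len(vals) and (vals.min() < -1e-12 or vals.max() > 1 + 1e-12):
            raise ValueError("rank scores must lie in [0, 1]")


@dataclass
class SubjectScore:
    id: str
    group: str
    allele_scores: tuple[float, float]
    biallelic: float
    imputed: bool
    unscoreable: bool = False


@dataclass
class CohortScores:
    """Per-subject biallelic damage scores for both structural contexts."""

    records: pd.DataFrame  # columns: id, group, score_dimer, score_monomer, ...

    def by_group(self, group: str, context: Context = "dimer") -> np.ndarray:
        col = f"score_{context}"
        ok = (self.records["group"] == group) & ~self.records["unscoreable"]
        return self.records.loc[ok, col].to_numpy(dtype=float)


def rank_normalize(
    values: Sequence[float],
    *,
    key: Literal["absolute", "signed"] = "absolute",
    scale: Literal["minmax", "fractional"] = "minmax",
) -> np.ndarray:
    """Map values to [0, 1] by fractional (average-tie) ranking.

    ``key="absolute"`` ranks |value| ascending, so the smallest-magnitude
    entry scores 0 and the largest 1. ``scale="minmax"`` rescales the
    average ranks so the extremes hit exactly 0 and 1 (ties at either end
    share the endpoint); ``"fractional"`` uses (rank − 1)/(N − 1).
    """
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1 or arr.size < 2:
        raise ValueError("rank normalisation requires at least two values")
    keyed = np.abs(arr) if key == "absolute" else arr
    ranks = rankdata(keyed, method="average")
    if scale == "minmax":
        lo, hi = ranks.min(), ranks.max()
        if hi == lo:  # all values tied: no ordering information
            return np.full(arr.shape, 0.5)
        return (ranks - lo) / (hi - lo)
    elif scale == "fractional":
        return (ranks - 1.0) / (arr.size - 1.0)
    raise ValueError(f"unknown scale {scale!r}")


def build_rank_table(
    ddg: DdgTable,
    *,
    key: Literal["absolute", "signed"] = "absolute",
    scale: Literal["minmax", "fractional"] = "minmax",
) -> RankScoreTable:
    """Rank-normalise a ΔΔG table into ΔΔG_rank scores.

    Each context is ranked over its own full set of entries; dimer and
    monomer tables are therefore normalised independently.
    """
    if len(ddg.entries) == 0:
        raise ValueError("empty ΔΔG table")
    keys = list(ddg.entries.keys())
    values = np.array([ddg.entries[k] for k in keys], dtype=float)
    if values.size == 1:
        scores = np.array([0.5])  # degenerate: single entry carries no ordering
    else:
        scores = rank_normalize(values, key=key, scale=scale)
    return RankScoreTable(
        context=ddg.context,
        scores=dict(zip(keys, scores.tolist())),
        covered_positions=ddg.covered_positions,
    )


def allele_score(
    allele: Allele,
    ranks: RankScoreTable,
    *,
    imputation: Literal["midpoint", "exclude"] = "midpoint",
) -> tuple[float | None, bool]:
    """Score one allele on [0, 1]; returns (score, imputed_flag).

    Wild type and synonymous → 0; truncating (null) → 1; missense → its
    ΔΔG_rank. A missense at a residue absent from the modelled structure
    has no ΔΔG; the default policy imputes the midpoint 0.5 and flags it,
    ``"exclude"`` returns (None, True) so callers can drop the subject.
    """
    if allele.kind is AlleleKind.WILD_TYPE:
        return 0.0, False
    v = allele.variant
    if v.consequence is Consequence.NULL:
        return 1.0, False
    if v.consequence is Consequence.SYNONYMOUS:
        return 0.0, False
    score = ranks.scores.get((v.position, v.alt_aa))
    if score is not None:
        return score, False
    if imputation == "midpoint":
        return 0.5, True
    return None, True


def biallelic_score(
    genotype: Genotype,
    ranks: RankScoreTable,
    *,
    imputation: Literal["midpoint", "exclude"] = "midpoint",
) -> tuple[float | None, bool]:
    """Mean of the two allele scores; (score, any_imputed)."""
    s1, f1 = allele_score(genotype.allele1, ranks, imputation=imputation)
    s2, f2 = allele_score(genotype.allele2, ranks, imputation=imputation)
    if s1 is None or s2 is None:
        return None, True
    return 0.5 * (s1 + s2), (f1 or f2)


def score_cohort(
    subjects: Iterable[Subject],
    ranks_dimer: RankScoreTable,
    ranks_monomer: RankScoreTable,
    *,
    imputation: Literal["midpoint", "exclude"] = "midpoint",
) -> CohortScores:
    """Score every subject in both contexts.

    Subjects that cannot be scored even by imputation are kept in the
    table with ``unscoreable=True`` (and NaN scores) and excluded from
    downstream statistics; a warning is emitted per dropped subject.
    """
    rows = []
    for s in subjects:
        rec: dict[str, object] = {"id": s.id, "group": s.group}
        unscoreable = False
        imputed = False
        for ctx, ranks in (("dimer", ranks_dimer), ("monomer", ranks_monomer)):
            a1, f1 = allele_score(s.genotype.allele1, ranks, imputation=imputation)
            a2, f2 = allele_score(s.genotype.allele2, ranks, imputation=imputation)
            if a1 is None or a2 is None:
                rec[f"score_{ctx}"] = np.nan
                rec[f"allele1_score_{ctx}"] = np.nan
                rec[f"allele2_score_{ctx}"] = np.nan
                unscoreable = True
            else:
                rec[f"score_{ctx}"] = 0.5 * (a1 + a2)
                rec[f"allele1_score_{ctx}"] = a1
                rec[f"allele2_score_{ctx}"] = a2
                imputed = imputed or f1 or f2
        rec["imputed"] = imputed
        rec["unscoreable"] = unscoreable
        if unscoreable:
            warnings.warn(
                f"subject {s.id}: allele not scoreable; excluded from statistics",
                stacklevel=2,
            )
        rows.append(rec)
    return CohortScores(records=pd.DataFrame(rows))


def normalize_predictor_scores(
    raw: Mapping[tuple[int, str], float],
    orientation: Literal["higher_is_damaging", "lower_is_damaging"],
    *,
    name: str = "predictor",
    scale: Literal["minmax", "fractional"] = "minmax",
) -> RankScoreTable:
    """Rank-normalise variant-effect-predictor scores onto the 0-1 scale.

    Uses the same fractional-rank machinery as the ΔΔG tables; scores with
    ``lower_is_damaging`` orientation are sign-flipped before ranking.
    """
    if orientation not in ("higher_is_damaging", "lower_is_damaging"):
        raise ValueError(f"unknown orientation {orientation!r}")
    keys = list(raw.keys())
    values = np.array([raw[k] for k in keys], dtype=float)
    if orientation == "lower_is_damaging":
        values = -values
    scores = rank_normalize(values, key="signed", scale=scale)
    return RankScoreTable(
        context=name,
        scores=dict(zip(keys, scores.tolist())),
        covered_positions=frozenset(pos for pos, _ in keys),
    )


# -- ΔΔG table I/O -----------------------------------------------------------

DDG_COLUMNS = ["position", "ref_aa", "alt_aa", "ddg_dimer", "ddg_monomer"]


def read_ddg_table(path: str | Path) -> tuple[DdgTable, DdgTable]:
    """Read a ΔΔG TSV (columns position, ref_aa, alt_aa, ddg_dimer,
    ddg_monomer; "NA" marks uncovered entries) into (dimer, monomer) tables."""
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    missing = set(DDG_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"ΔΔG table missing columns {sorted(missing)}")
    tables = []
    for ctx, col in (("dimer", "ddg_dimer"), ("monomer", "ddg_monomer")):
        sub = df.dropna(subset=[col])
        entries = {
            (int(r.position), str(r.alt_aa)): float(getattr(r, col))
            for r in sub.itertuples()
        }
        covered = frozenset(int(p) for p in sub["position"].unique())
        ref = {int(r.position): str(r.ref_aa) for r in sub.itertuples()}
        tables.append(DdgTable(ctx, entries, covered, ref))
    return tables[0], tables[1]


def write_ddg_table(dimer: DdgTable, monomer: DdgTable, path: str | Path) -> None:
    keys = sorted(set(dimer.entries) | set(monomer.entries))
    ref = {**monomer.ref_aa, **dimer.ref_aa}
    rows = [
        {
            "position": pos,
            "ref_aa": ref.get(pos, "X"),
            "alt_aa": alt,
            "ddg_dimer": dimer.entries.get((pos, alt), np.nan),
            "ddg_monomer": monomer.entries.get((pos, alt), np.nan),
        }
        for pos, alt in keys
    ]
    pd.DataFrame(rows, columns=DDG_COLUMNS).to_csv(
        path, sep="\t", index=False, na_rep="NA", float_format="%.6g"
    )


def write_cohort_scores(scores: CohortScores, path: str | Path) -> None:
    cols = [
        "id", "group", "score_dimer", "score_monomer",
        "allele1_score_dimer", "allele2_score_dimer",
        "allele1_score_monomer", "allele2_score_monomer",
        "imputed", "unscoreable",
    ]
    scores.records.loc[:, cols].to_csv(path, sep="\t", index=False, float_format="%.6g")
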