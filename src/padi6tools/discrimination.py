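"""Phenotype discrimination (ROC AUC) and rank-based group comparisons.

The AUC is computed by the Mann-Whitney pair-counting identity
AUC = [#(pos > neg) + 0.5 #(pos == neg)] / (n_pos * n_neg), not by
integrating an empirical ROC curve: the identity is exact, handles ties,
and matches the interpretation that 0.5 is chance and 1 is perfect
discrimination.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, rankdata

from .damage import CohortScores, RankScoreTable, allele_score
from .variants import Subject


@dataclass(frozen=True)
class RocResult:
    auc: float
    n_pos: int
    n_neg: int
    tie_count: int  # number of tied cross-group pairs


@dataclass(frozen=True)
class GroupComparison:
    statistic: float  # Mann-Whitney U of group a vs group b
    p_value: float
    direction: Literal["a_higher", "b_higher", "none"]
    method: str


def roc_auc(scores_pos: Sequence[float], scores_neg: Sequence[float]) -> RocResult:
    """ROC AUC by exact pair counting (ties count one half)."""
    pos = np.asarray(scores_pos, dtype=float)
    neg = np.asarray(scores_neg, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both groups must be non-empty")
    # U statistic via joint ranking: O((n+m) log(n+m)) and tie-exact
    joint = np.concatenate([pos, neg])
    ranks = rankdata(joint, method="average")
    u = ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2.0
    ties = 0
    # tie count needs the actual equal cross pairs
    pv, pc = np.unique(pos, return_counts=True)
    nv, nc = np.unique(neg, return_counts=True)
    common, pi, ni = np.intersect1d(pv, nv, return_indices=True)
    if common.size:
        ties = int((pc[pi] * nc[ni]).sum())
    return RocResult(
        auc=float(u / (pos.size * neg.size)),
        n_pos=int(pos.size),
        n_neg=int(neg.size),
        tie_count=ties,
    )


def group_comparison(
    scores_a: Sequence[float],
    scores_b: Sequence[float],
    alternative: Literal["greater", "less", "two_sided"] = "greater",
    *,
    exact_limit: int = 10_000,
) -> GroupComparison:
    """Mann-Whitney U rank-sum comparison of two score groups.

    Uses exact enumeration when the sample is tie-free and
    ``n_a * n_b <= exact_limit``; otherwise the tie-corrected normal
    approximation (with continuity correction).
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    method = "exact" if (not has_ties and a.size * b.size <= exact_limit) else "asymptotic"
    alt = alternative.replace("_", "-")
    res = mannwhitneyu(a, b, alternative=alt, method=method)
    mean_u = a.size * b.size / 2.0
    if res.statistic > mean_u:
        direction = "a_higher"
    elif res.statistic < mean_u:
        direction = "b_higher"
    else:
        direction = "none"
    return GroupComparison(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        direction=direction,
        method=method,
    )


def _subject_biallelic(
    subject: Subject, ranks: RankScoreTable
) -> tuple[float | None, bool]:
    s1, f1 = allele_score(subject.genotype.allele1, ranks, imputation="exclude")
    s2, f2 = allele_score(subject.genotype.allele2, ranks, imputation="exclude")
    if s1 is None or s2 is None:
        return None, True
    return 0.5 * (s1 + s2), (f1 or f2)


def compare_predictors(
    subjects: Sequence[Subject],
    scorers: Mapping[str, RankScoreTable],
    pos_group: str = "infertility",
    neg_group: str = "MLID",
) -> pd.DataFrame:
    """AUC of each named scorer at separating pos_group from neg_group.

    All scorers are evaluated on the identical subject subset: a subject
    dropped for missing coverage under any scorer is dropped from all
    (paired comparison). Returns a table with one row per scorer.
    """
    if not scorers:
        raise ValueError("no scorers supplied")
    cohort = [s for s in subjects if s.group in (pos_group, neg_group)]
    if not cohort:
        raise ValueError(f"no subjects in groups {pos_group!r}/{neg_group!r}")
    per_scorer: dict[str, dict[str, float]] = {}
    keep = [s.id for s in cohort]
    for name, ranks in scorers.items():
        scored: dict[str, float] = {}
        for s in cohort:
            val, _ = _subject_biallelic(s, ranks)
            if val is not None:
                scored[s.id] = val
        if not scored:
            raise ValueError(f"scorer {name!r} covers no subject alleles")
        per_scorer[name] = scored
        keep = [sid for sid in keep if sid in scored]
    if not keep:
        raise ValueError("no subject is covered by every scorer")
    group_of = {s.id: s.group for s in cohort}
    rows = []
    for name, scored in per_scorer.items():
        pos = [scored[sid] for sid in keep if group_of[sid] == pos_group]
        neg = [scored[sid] for sid in keep if group_of[sid] == neg_group]
        r = roc_auc(pos, neg)
        rows.append(
            {"scorer": name, "auc": r.auc, "n_pos": r.n_pos, "n_neg": r.n_neg,
             "tie_pairs": r.tie_count}
        )
    return pd.DataFrame(rows)


def cohort_auc(
    scores: CohortScores,
    pos_group: str = "infertility",
    neg_group: str = "MLID",
    context: Literal["dimer", "monomer"] = "dimer",
) -> RocResult:
    """AUC between two groups of an already-scored cohort."""
    return roc_auc(scores.by_group(pos_group, context), scores.by_group(neg_group, context))
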