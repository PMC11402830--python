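"""End-to-end orchestration: scoring runs and structure reports.

A run consumes plain-text inputs (ΔΔG TSV, cohort TSV, optional predictor
TSVs, PDB/mmCIF files), executes the scoring or structural analyses, and
writes machine-readable outputs plus a provenance log naming the inputs,
parameters and the configuration hash, so re-running an identical
configuration reproduces the reports byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Sequence

import pandas as pd

from . import __version__
from .damage import (
    CohortScores,
    build_rank_table,
    normalize_predictor_scores,
    read_ddg_table,
    score_cohort,
    write_cohort_scores,
)
from .discrimination import GroupComparison, compare_predictors, group_comparison
from .structure import (
    StructureModel,
    align_and_rmsd,
    atom_distance,
    interface_stats,
    read_structure,
    region_bfactor_mean,
)
from .variants import read_cohort_table


@dataclass(frozen=True)
class ScoringConfig:
    ddg_table: str
    cohort_table: str
    predictor_tables: Mapping[str, tuple[str, str]] = field(default_factory=dict)
    # name -> (path, orientation in {higher_is_damaging, lower_is_damaging})
    ranking_key: Literal["absolute", "signed"] = "absolute"
    scale: Literal["minmax", "fractional"] = "minmax"
    imputation: Literal["midpoint", "exclude"] = "midpoint"
    pos_group: str = "infertility"
    neg_group: str = "MLID"
    control_groups: tuple[str, ...] = ("gnomad_het", "gnomad_hom", "primad_hom")
    out_dir: str | None = None


@dataclass
class ScoringResult:
    scores: CohortScores
    auc_table: pd.DataFrame
    comparisons: pd.DataFrame
    config_hash: str


def _config_hash(config) -> str:
    payload = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _provenance(config, extra: dict) -> dict:
    return {
        "tool": f"padi6tools {__version__}",
        "config": dataclasses.asdict(config),
        "config_hash": _config_hash(config),
        **extra,
    }


def run_scoring_pipeline(config: ScoringConfig) -> ScoringResult:
    """Rank-normalise ΔΔG tables, score the cohort, and report discrimination.

    Outputs (when ``out_dir`` is set): per-subject scores TSV, AUC report
    TSV (dimer, monomer and each predictor on the identical subject set),
    pairwise group-comparison TSV, and a provenance JSON.
    """
    for p in [config.ddg_table, config.cohort_table] + [
        p for p, _ in config.predictor_tables.values()
    ]:
        if not Path(p).exists():
            raise FileNotFoundError(f"input not found: {p}")
    dimer_ddg, monomer_ddg = read_ddg_table(config.ddg_table)
    ranks_dimer = build_rank_table(dimer_ddg, key=config.ranking_key, scale=config.scale)
    ranks_monomer = build_rank_table(monomer_ddg, key=config.ranking_key, scale=config.scale)
    subjects = read_cohort_table(config.cohort_table)

    scores = score_cohort(
        subjects, ranks_dimer, ranks_monomer, imputation=config.imputation
    )

    scorers = {"dimer": ranks_dimer, "monomer": ranks_monomer}
    for name, (path, orientation) in config.predictor_tables.items():
        df = pd.read_csv(path, sep="\t")
        raw = {
            (int(r.position), str(r.alt_aa)): float(r.score) for r in df.itertuples()
        }
        scorers[name] = normalize_predictor_scores(
            raw, orientation, name=name, scale=config.scale
        )
    auc_table = compare_predictors(
        subjects, scorers, pos_group=config.pos_group, neg_group=config.neg_group
    )

    control = []
    for g in config.control_groups:
        control.extend(scores.by_group(g, "dimer").tolist())
    comp_rows = []
    pairs = [
        (config.pos_group, config.neg_group,
         scores.by_group(config.pos_group, "dimer"),
         scores.by_group(config.neg_group, "dimer")),
    ]
    if control:
        pairs.append((config.pos_group, "controls",
                      scores.by_group(config.pos_group, "dimer"), control))
        pairs.append((config.neg_group, "controls",
                      scores.by_group(config.neg_group, "dimer"), control))
    for name_a, name_b, a, b in pairs:
        if len(a) == 0 or len(b) == 0:
            continue
        c: GroupComparison = group_comparison(a, b, "greater")
        comp_rows.append(
            {"group_a": name_a, "group_b": name_b, "n_a": len(a), "n_b": len(b),
             "U": c.statistic, "p_greater": c.p_value, "method": c.method}
        )
    comparisons = pd.DataFrame(comp_rows)

    result = ScoringResult(
        scores=scores,
        auc_table=auc_table,
        comparisons=comparisons,
        config_hash=_config_hash(config),
    )
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_cohort_scores(scores, out / "scores.tsv")
        auc_table.to_csv(out / "auc_report.tsv", sep="\t", index=False, float_format="%.6g")
        comparisons.to_csv(out / "group_comparisons.tsv", sep="\t", index=False,
                           float_format="%.6g")
        prov = _provenance(config, {
            "n_subjects": len(scores.records),
            "n_unscoreable": int(scores.records["unscoreable"].sum()),
            "outputs": ["scores.tsv", "auc_report.tsv", "group_comparisons.tsv"],
        })
        (out / "provenance.json").write_text(json.dumps(prov, indent=2, default=str) + "\n")
    return result


@dataclass(frozen=True)
class StructureReportConfig:
    structures: Mapping[str, str]  # label -> path
    bfactor_regions: Sequence[tuple[str, str, int | None, int | None]] = ()
    # (structure label, chain, first_res, last_res); None bounds = whole chain
    rmsd_pairs: Sequence[tuple[str, str, str, str]] = ()
    # (label_a, chain_a, label_b, chain_b)
    distances: Sequence[tuple[str, str, str]] = ()
    # (structure label, selector_a, selector_b)
    interface_chains: Sequence[tuple[str, str, str]] = ()
    # (structure label, chain_a, chain_b)
    cycles: int = 5
    reject_cutoff: float = 2.0
    out_dir: str | None = None


def run_structure_report(config: StructureReportConfig) -> pd.DataFrame:
    """Compute the requested structural metrics as one tidy table.

    Rows carry ``metric`` in {bfactor_all, bfactor_main_chain, rmsd,
    distance, interface_area, interface_residues}, a human-readable
    ``target`` and the numeric ``value``.
    """
    models: dict[str, StructureModel] = {}
    for label, path in config.structures.items():
        if not Path(path).exists():
            raise FileNotFoundError(f"structure {label}: {path} not found")
        models[label] = read_structure(path)
    rows = []
    for label, chain, first, last in config.bfactor_regions:
        for sel, metric in (("all_atoms", "bfactor_all"), ("main_chain", "bfactor_main_chain")):
            val = region_bfactor_mean(models[label], chain, first, last, sel)
            rows.append({"metric": metric,
                         "target": f"{label}/{chain}:{first or 'start'}-{last or 'end'}",
                         "value": val, "unit": "A^2"})
    for la, ca, lb, cb in config.rmsd_pairs:
        sup = align_and_rmsd(models[la], models[lb], ca, cb,
                             cycles=config.cycles, reject_cutoff=config.reject_cutoff)
        rows.append({"metric": "rmsd", "target": f"{la}:{ca} vs {lb}:{cb}",
                     "value": sup.rmsd, "unit": "A", "n_pairs": sup.n_pairs,
                     "rejected": sup.rejected_pairs})
    for label, sa, sb in config.distances:
        rows.append({"metric": "distance", "target": f"{label} {sa}..{sb}",
                     "value": atom_distance(models[label], sa, sb), "unit": "A"})
    for label, ca, cb in config.interface_chains:
        st = interface_stats(models[label], ca, cb)
        rows.append({"metric": "interface_area", "target": f"{label} {ca}|{cb}",
                     "value": st.buried_area, "unit": "A^2"})
        rows.append({"metric": "interface_residues", "target": f"{label} {ca}|{cb}",
                     "value": st.total_residues_at_interface, "unit": "count"})
    report = pd.DataFrame(rows)
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        report.to_csv(out / "structure_report.tsv", sep="\t", index=False,
                      float_format="%.6g")
        prov = _provenance(config, {"outputs": ["structure_report.tsv"]})
        (out / "provenance.json").write_text(json.dumps(prov, indent=2, default=str) + "\n")
    return report
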