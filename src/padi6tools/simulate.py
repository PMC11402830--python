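"""Seeded synthetic-data generators for every pipeline stage.

These generators stand in for the study's real inputs — a stability-change
(ΔΔG) scan of every possible missense variant, patient/control cohorts,
deposited coordinates and the multi-species orthologue alignment — with
the statistical structure the analysis assumes, so the full pipeline is
testable offline:

* a ΔΔG landscape with a buried/surface mixture of gamma-distributed
  magnitudes and an interface-specific excess in the dimer context;
* cohorts in which infertility genotypes are enriched for damaging and
  truncating alleles, MLID genotypes carry at most one enriched allele
  (fertile-carrier model), and gnomAD/primAD controls follow het/hom
  mechanics;
* a CA-bead toy dimer with a designed contact patch;
* a toy orthologue alignment with designed conservation counts.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .conservation import AA20, MultipleAlignment
from .damage import DdgTable, RankScoreTable
from .structure import StructureModel, SuperpositionResult, _ATOM_COLUMNS
from .variants import (
    Allele,
    Consequence,
    Genotype,
    ProteinVariant,
    Subject,
)

#: per-group (allele1, allele2) probabilities that a patient allele is drawn
#: from the top decile of ΔΔG_rank. Infertility damage is modelled as
#: recessive (both alleles enriched); MLID subjects are fertile carriers, so
#: enrichment applies to at most one allele; controls are unenriched.
DEFAULT_TOP_DECILE_P: dict[str, tuple[float, float]] = {
    "infertility": (0.9, 0.9),
    "HM": (0.6, 0.3),
    "MLID": (0.3, 0.0),
    "gnomad_het": (0.0, 0.0),
    "gnomad_hom": (0.0, 0.0),
    "primad_hom": (0.0, 0.0),
}

#: per-group per-allele probability of a truncating (null) allele.
DEFAULT_NULL_P: dict[str, tuple[float, float]] = {
    "infertility": (0.2, 0.2),
    "HM": (0.1, 0.0),
    "MLID": (0.0, 0.0),
    "gnomad_het": (0.0, 0.0),
    "gnomad_hom": (0.0, 0.0),
    "primad_hom": (0.0, 0.0),
}

#: cohort sizes at the scale of the study (26 infertility cases, 9 MLID
#: carrier families; control set sizes are nominal).
DEFAULT_GROUP_SIZES: dict[str, int] = {
    "infertility": 26,
    "HM": 3,
    "MLID": 9,
    "gnomad_het": 30,
    "gnomad_hom": 10,
    "primad_hom": 20,
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of all synthetic generators (seeded, deterministic)."""

    seed: int = 0
    n_residues: int = 300
    interface_fraction: float = 0.105
    buried_fraction: float = 0.25
    # gamma-distributed |ΔΔG| magnitudes per residue class (kcal/mol)
    buried_shape: float = 2.0
    buried_scale: float = 1.6
    surface_shape: float = 1.2
    surface_scale: float = 0.7
    sign_flip_p: float = 0.08  # stabilising variants exist
    interface_dimer_excess: float = 3.0  # kcal/mol added in the dimer context
    context_noise_sd: float = 0.1
    group_sizes: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_SIZES)
    )
    top_decile_p: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_TOP_DECILE_P)
    )
    null_p: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_NULL_P)
    )
    top_decile: float = 0.9  # rank threshold defining a "damaging" draw
    interface_targeted: bool = False  # draw patient damaging alleles at the interface

    def with_seed(self, seed: int) -> "GeneratorConfig":
        return replace(self, seed=seed)


def _rng(config_seed: int, stream: int, seed: int | None = None) -> np.random.Generator:
    # fixed stream-splitting: adding a generator never shifts others' draws
    return np.random.default_rng([seed if seed is not None else config_seed, stream])


@dataclass
class SimulatedLandscape:
    dimer: DdgTable
    monomer: DdgTable
    interface_positions: frozenset[int]
    buried_positions: frozenset[int]
    reference_seq: dict[int, str]


def simulate_ddg_landscape(
    config: GeneratorConfig, seed: int | None = None
) -> SimulatedLandscape:
    """Generate (dimer, monomer) ΔΔG tables over all 19 substitutions/residue.

    Monomer ΔΔG magnitudes are gamma draws (heavier for buried residues)
    with a small sign-flip probability; the dimer context equals the
    monomer plus ``interface_dimer_excess`` at interface residues and small
    noise elsewhere.
    """
    if config.n_residues < 2:
        raise ValueError("need at least 2 residues")
    rng = _rng(config.seed, 1, seed)
    n = config.n_residues
    positions = np.arange(1, n + 1)
    ref_idx = rng.integers(0, 20, size=n)
    ref_seq = {int(p): AA20[i] for p, i in zip(positions, ref_idx)}
    n_iface = max(1, round(config.interface_fraction * n))
    interface = frozenset(
        int(p) for p in rng.choice(positions, size=n_iface, replace=False)
    )
    remaining = np.array([p for p in positions if p not in interface])
    n_buried = max(1, round(config.buried_fraction * n))
    buried = frozenset(
        int(p) for p in rng.choice(remaining, size=min(n_buried, len(remaining)), replace=False)
    )
    dimer_entries: dict[tuple[int, str], float] = {}
    mono_entries: dict[tuple[int, str], float] = {}
    for pos in positions:
        pos = int(pos)
        ref = ref_seq[pos]
        if pos in buried:
            mags = rng.gamma(config.buried_shape, config.buried_scale, size=19)
        else:
            mags = rng.gamma(config.surface_shape, config.surface_scale, size=19)
        signs = np.where(rng.random(19) < config.sign_flip_p, -1.0, 1.0)
        mono = mags * signs
        noise = rng.normal(0.0, config.context_noise_sd, size=19)
        excess = config.interface_dimer_excess if pos in interface else 0.0
        dim = mono + excess + noise
        alts = [a for a in AA20 if a != ref]
        for alt, m, d in zip(alts, mono, dim):
            mono_entries[(pos, alt)] = float(m)
            dimer_entries[(pos, alt)] = float(d)
    covered = frozenset(int(p) for p in positions)
    ref_map = dict(ref_seq)
    return SimulatedLandscape(
        dimer=DdgTable("dimer", dimer_entries, covered, dict(ref_map)),
        monomer=DdgTable("monomer", mono_entries, covered, dict(ref_map)),
        interface_positions=interface,
        buried_positions=buried,
        reference_seq=ref_map,
    )


def _draw_missense(
    rng: np.random.Generator,
    keys: Sequence[tuple[int, str]],
    ref_seq: Mapping[int, str],
) -> Allele:
    pos, alt = keys[rng.integers(0, len(keys))]
    ref = ref_seq.get(pos, "A")
    if ref == alt:  # cannot happen for generated tables; guard for custom input
        alt = next(a for a in AA20 if a != ref)
    return Allele.of(ProteinVariant(pos, ref, alt, Consequence.MISSENSE))


def _draw_null(rng: np.random.Generator, ref_seq: Mapping[int, str]) -> Allele:
    positions = sorted(ref_seq)
    pos = int(positions[rng.integers(0, len(positions))])
    return Allele.of(ProteinVariant(pos, ref_seq[pos], None, Consequence.NULL))


def simulate_cohort(
    config: GeneratorConfig,
    ranks_dimer: RankScoreTable,
    landscape: SimulatedLandscape | None = None,
    seed: int | None = None,
) -> list[Subject]:
    """Generate subjects with known, group-specific damage enrichment.

    Each patient allele is, independently: a truncating allele with the
    group's null probability; otherwise a draw from the top decile of the
    dimer ΔΔG_rank with the group's enrichment probability (restricted to
    interface residues when ``interface_targeted``); otherwise a uniform
    background missense. gnomAD heterozygotes get one variant plus wild
    type; homozygote sets get two copies of one draw.
    """
    rng = _rng(config.seed, 2, seed)
    ref_seq = (
        landscape.reference_seq
        if landscape is not None
        else {pos: "A" for pos in ranks_dimer.covered_positions}
    )
    all_keys = sorted(ranks_dimer.scores)
    top_keys = sorted(
        k for k, v in ranks_dimer.scores.items() if v >= config.top_decile
    )
    if not top_keys:
        raise ValueError("no variants in the top decile; rank table too small")
    iface_top = top_keys
    if config.interface_targeted and landscape is not None:
        iface_top = [k for k in top_keys if k[0] in landscape.interface_positions]
        if not iface_top:
            raise ValueError("no interface variants in the top decile")

    def patient_allele(group: str, slot: int) -> Allele:
        if rng.random() < config.null_p[group][slot]:
            return _draw_null(rng, ref_seq)
        if rng.random() < config.top_decile_p[group][slot]:
            pool = iface_top if (config.interface_targeted and group == "infertility") else top_keys
            return _draw_missense(rng, pool, ref_seq)
        return _draw_missense(rng, all_keys, ref_seq)

    subjects: list[Subject] = []
    counter = 0
    for group, size in config.group_sizes.items():
        for _ in range(size):
            counter += 1
            sid = f"S{counter:04d}_{group}"
            if group == "gnomad_het":
                g = Genotype(_draw_missense(rng, all_keys, ref_seq), Allele.wild_type())
            elif group.endswith("_hom"):
                a = _draw_missense(rng, all_keys, ref_seq)
                g = Genotype(a, a)
            else:
                g = Genotype(patient_allele(group, 0), patient_allele(group, 1))
            subjects.append(Subject(sid, g, group))
    return subjects


# -- toy structures ----------------------------------------------------------


@dataclass
class ToyDimer:
    model: StructureModel
    contact_residues_a: frozenset[int]
    contact_residues_b: frozenset[int]
    applied_rotation: np.ndarray | None = None
    applied_translation: np.ndarray | None = None


def simulate_toy_dimer(
    n_residues: int = 40,
    patch_start: int = 15,
    patch_size: int = 12,
    separation: float = 5.5,
    *,
    seed: int | None = None,
    random_transform: bool = False,
    spacing: float = 3.8,
) -> ToyDimer:
    """A two-chain CA-bead fixture with a designed contact patch.

    Chain A is a straight bead chain (one CA per residue, ``spacing`` Å
    apart). Chain B spans only the contact patch, placed ``separation`` Å
    above residues ``patch_start .. patch_start+patch_size-1``. With the
    default 1.7 Å carbon radius and 1.4 Å probe, beads closer than 6.2 Å
    bury surface, so separations below that create exactly the designed
    interface; 100 Å separates the chains completely.
    """
    if patch_start + patch_size - 1 > n_residues:
        raise ValueError("contact patch extends beyond chain A")
    rows = []
    b_base = 20.0
    # slight zig-zag in y keeps the chains non-collinear (superposable)
    # without changing which bead pairs are within surface-burial reach
    def wiggle(resnum: int) -> float:
        return 0.5 if resnum % 2 else -0.5

    for i in range(n_residues):
        resnum = i + 1
        rows.append(
            ("A", resnum, "", "ALA", "CA", "C",
             i * spacing, wiggle(resnum), 0.0, b_base + resnum, 1.0, "", False, False)
        )
    for j in range(patch_size):
        resnum = patch_start + j
        rows.append(
            ("B", resnum, "", "ALA", "CA", "C",
             (resnum - 1) * spacing, wiggle(resnum), separation, b_base, 1.0, "", False, False)
        )
    model = StructureModel(pd.DataFrame(rows, columns=_ATOM_COLUMNS), source="toy_dimer")
    rot = trans = None
    if random_transform:
        rng = _rng(seed if seed is not None else 0, 3, seed)
        # random proper rotation via QR of a Gaussian matrix
        q, r = np.linalg.qr(rng.normal(size=(3, 3)))
        q *= np.sign(np.diag(r))
        if np.linalg.det(q) < 0:
            q[:, 0] *= -1
        trans = rng.uniform(-20, 20, size=3)
        rot = q
        sup = SuperpositionResult(rotation=rot, translation=trans, rmsd=0.0, n_pairs=0)
        model = model.transformed(sup)
    patch = frozenset(range(patch_start, patch_start + patch_size))
    return ToyDimer(
        model=model,
        contact_residues_a=patch,
        contact_residues_b=patch,
        applied_rotation=rot,
        applied_translation=trans,
    )


def simulate_helix_chain(
    n_residues: int = 60, *, chain: str = "A", rise: float = 1.5,
    radius: float = 2.3, turn_deg: float = 100.0, b_factor: float = 30.0,
) -> StructureModel:
    """A single ideal-helix CA trace (a convenient non-collinear fixture)."""
    rows = []
    for i in range(n_residues):
        ang = np.deg2rad(turn_deg * i)
        rows.append(
            (chain, i + 1, "", "ALA", "CA", "C",
             radius * np.cos(ang), radius * np.sin(ang), rise * i,
             b_factor, 1.0, "", False, False)
        )
    return StructureModel(pd.DataFrame(rows, columns=_ATOM_COLUMNS), source="toy_helix")


# -- toy alignments ----------------------------------------------------------


def simulate_alignment(
    n_sequences: int = 80,
    n_columns: int = 120,
    substitution_p: float = 0.05,
    *,
    seed: int | None = None,
    designed_counts: Mapping[int, int] | None = None,
    stop_sequences: Sequence[int] = (),
    missing_run_sequences: Sequence[int] = (),
    missing_run_length: int = 50,
    reference_id: str = "hPADI6",
) -> MultipleAlignment:
    """An ungapped toy orthologue alignment with designed conservation.

    ``designed_counts`` maps a reference position to the exact number of
    sequences (reference included) that carry the reference residue there;
    the remainder get a single alternative residue. ``stop_sequences`` and
    ``missing_run_sequences`` corrupt chosen non-reference sequences with
    two internal stops / a gap run, for exercising the quality filter.
    """
    rng = _rng(seed if seed is not None else 0, 4, seed)
    ref = "".join(AA20[i] for i in rng.integers(0, 20, size=n_columns))
    seqs = [list(ref)]
    for _ in range(n_sequences - 1):
        chars = list(ref)
        for c in range(n_columns):
            if rng.random() < substitution_p:
                alt = AA20[rng.integers(0, 20)]
                while alt == ref[c]:
                    alt = AA20[rng.integers(0, 20)]
                chars[c] = alt
        seqs.append(chars)
    for pos, n_match in (designed_counts or {}).items():
        col = pos - 1
        if not (0 <= col < n_columns):
            raise ValueError(f"designed position {pos} outside alignment")
        if not (1 <= n_match <= n_sequences):
            raise ValueError(f"designed count {n_match} outside 1..{n_sequences}")
        alt = next(a for a in AA20 if a != ref[col])
        for i in range(n_sequences):
            seqs[i][col] = ref[col] if i < n_match else alt
    for i in stop_sequences:
        if i == 0:
            raise ValueError("will not corrupt the reference sequence")
        seqs[i][n_columns // 3] = "*"
        seqs[i][2 * n_columns // 3] = "*"
    for i in missing_run_sequences:
        if i == 0:
            raise ValueError("will not corrupt the reference sequence")
        start = n_columns // 4
        for c in range(start, min(start + missing_run_length, n_columns)):
            seqs[i][c] = "X"
    ids = [reference_id] + [f"species_{i:02d}" for i in range(1, n_sequences)]
    return MultipleAlignment(ids, ["".join(s) for s in seqs], reference_id)
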