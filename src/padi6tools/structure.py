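"""Coordinate-level structural analyses.

Parsing (PDB/mmCIF via gemmi), Kabsch least-squares superposition, Cα
alignment with iterative outlier rejection, regional B-factor means,
interatomic distances, Shrake-Rupley solvent-accessible surface area and
dimer-interface statistics.

Conventions: residue ranges are inclusive and use author numbering;
main-chain atoms are {N, CA, C, O}; waters and heteroatoms are retained in
the model but excluded from B-factor and surface-area calculations by
default; alternate locations are resolved to the highest-occupancy
conformer (ties broken alphabetically).
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Sequence

import gemmi
import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

#: element -> van der Waals radius (Å) used for surface calculations.
#: Hydrogens are normally absent from X-ray models and simply not counted.
VDW_RADII = {
    "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "H": 1.20,
    "P": 1.80, "SE": 1.90,
}

MAIN_CHAIN_ATOMS = ("N", "CA", "C", "O")

_ATOM_COLUMNS = [
    "chain", "resnum", "icode", "resname", "atom", "element",
    "x", "y", "z", "b", "occ", "altloc", "het", "water",
]


class SelectorError(ValueError):
    """An atom selector resolved to zero or more than one atom."""


@dataclass
class StructureModel:
    """Parsed atomic coordinates as a flat atom table."""

    atoms: pd.DataFrame
    source: str = ""

    @property
    def chains(self) -> list[str]:
        return list(dict.fromkeys(self.atoms["chain"]))

    def polymer(self) -> pd.DataFrame:
        a = self.atoms
        return a[~a["het"] & ~a["water"]]

    def select(
        self,
        chain: str | None = None,
        first_res: int | None = None,
        last_res: int | None = None,
        atom_names: Sequence[str] | None = None,
        include_het: bool = False,
    ) -> pd.DataFrame:
        df = self.atoms if include_het else self.polymer()
        if chain is not None:
            df = df[df["chain"] == chain]
        if first_res is not None:
            df = df[df["resnum"] >= first_res]
        if last_res is not None:
            df = df[df["resnum"] <= last_res]
        if atom_names is not None:
            df = df[df["atom"].isin(atom_names)]
        return df

    def coords(self, df: pd.DataFrame | None = None) -> np.ndarray:
        if df is None:
            df = self.polymer()
        return df[["x", "y", "z"]].to_numpy(dtype=float)

    def ca_trace(self, chain: str) -> tuple[np.ndarray, str, np.ndarray]:
        """(residue numbers, one-letter sequence, Cα coordinates) for a chain."""
        df = self.select(chain=chain, atom_names=["CA"])
        df = df.sort_values(["resnum", "icode"], kind="stable")
        seq = "".join(_one_letter(rn) for rn in df["resname"])
        return df["resnum"].to_numpy(int), seq, self.coords(df)

    def residue_count(self, chain: str | None = None) -> int:
        df = self.polymer()
        if chain is not None:
            df = df[df["chain"] == chain]
        return len(df.groupby(["chain", "resnum", "icode"], sort=False))

    def subset(self, chains: Sequence[str]) -> "StructureModel":
        return StructureModel(
            self.atoms[self.atoms["chain"].isin(chains)].reset_index(drop=True),
            source=self.source,
        )

    def transformed(self, sup: "SuperpositionResult") -> "StructureModel":
        atoms = self.atoms.copy()
        xyz = atoms[["x", "y", "z"]].to_numpy(dtype=float)
        atoms[["x", "y", "z"]] = xyz @ sup.rotation.T + sup.translation
        return StructureModel(atoms, source=self.source)


def _one_letter(resname: str) -> str:
    info = gemmi.find_tabulated_residue(resname)
    if info is not None and info.is_amino_acid():
        return info.one_letter_code.upper()
    return "X"


def read_structure(
    source: str | Path,
    format: Literal["auto", "PDB", "mmCIF"] = "auto",
) -> StructureModel:
    """Parse a PDB or mmCIF file (path, or raw text containing newlines).

    Alternate locations are resolved to one atom per (chain, residue,
    atom name): highest occupancy wins, ties go to the alphabetically
    first altloc. Waters and heteroatoms are tagged but retained.
    """
    text_input = isinstance(source, str) and "\n" in source
    try:
        if text_input:
            if format == "mmCIF" or (format == "auto" and source.lstrip().startswith("data_")):
                doc = gemmi.cif.read_string(source)
                st = gemmi.make_structure_from_block(doc.sole_block())
            else:
                st = gemmi.read_pdb_string(source)
        else:
            path = Path(source)
            if not path.exists():
                raise FileNotFoundError(path)
            if format == "PDB":
                st = gemmi.read_pdb(str(path))
            elif format == "mmCIF":
                doc = gemmi.cif.read(str(path))
                st = gemmi.make_structure_from_block(doc.sole_block())
            else:
                st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as err:
        raise ValueError(f"unparseable structure input: {err}") from err
    st.setup_entities()
    rows = []
    model = st[0]
    for chain in model:
        for res in chain:
            het = res.het_flag == "H"
            water = res.is_water()
            # altloc resolution: keep best conformer per atom name
            best: dict[str, gemmi.Atom] = {}
            for atom in res:
                cur = best.get(atom.name)
                if (
                    cur is None
                    or atom.occ > cur.occ
                    or (atom.occ == cur.occ and atom.altloc < cur.altloc)
                ):
                    best[atom.name] = atom
            for atom in best.values():
                rows.append(
                    (
                        chain.name, res.seqid.num, res.seqid.icode.strip(),
                        res.name, atom.name, atom.element.name.upper(),
                        atom.pos.x, atom.pos.y, atom.pos.z,
                        atom.b_iso, atom.occ, atom.altloc.strip(),
                        het and not water, water,
                    )
                )
    df = pd.DataFrame(rows, columns=_ATOM_COLUMNS)
    if df.empty:
        raise ValueError("no atoms parsed from structure input")
    if not np.isfinite(df[["x", "y", "z"]].to_numpy(dtype=float)).all():
        raise ValueError("non-finite coordinates in structure")
    return StructureModel(df, source=st.name or str(source)[:40])


# -- superposition -----------------------------------------------------------


@dataclass
class SuperpositionResult:
    rotation: np.ndarray  # 3x3 proper rotation
    translation: np.ndarray  # length-3
    rmsd: float
    n_pairs: int
    rejected_pairs: int = 0

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, float) @ self.rotation.T + self.translation


def kabsch_superpose(coords_ref: np.ndarray, coords_mov: np.ndarray) -> SuperpositionResult:
    """Least-squares optimal rigid superposition of mov onto ref (Kabsch).

    Reflections are excluded: the returned rotation is proper
    (determinant +1). Requires >= 3 non-degenerate paired points.
    """
    P = np.asarray(coords_ref, dtype=float)
    Q = np.asarray(coords_mov, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("coordinate arrays must be matching (n, 3)")
    n = P.shape[0]
    if n < 3:
        raise ValueError("superposition requires at least 3 points")
    cp, cq = P.mean(axis=0), Q.mean(axis=0)
    H = (Q - cq).T @ (P - cp)
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    if S[1] < 1e-10 * max(S[0], 1.0):
        raise ValueError("degenerate (collinear) geometry")
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cp - R @ cq
    moved = Q @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - P) ** 2, axis=1))))
    return SuperpositionResult(rotation=R, translation=t, rmsd=rmsd, n_pairs=n)


def _pair_ca_by_alignment(
    trace_a: tuple[np.ndarray, str, np.ndarray],
    trace_b: tuple[np.ndarray, str, np.ndarray],
    *,
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Pair Cα coordinates via global sequence alignment (BLOSUM62, affine gaps)."""
    from Bio import Align
    from Bio.Align import substitution_matrices

    _, seq_a, xyz_a = trace_a
    _, seq_b, xyz_b = trace_b
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    aligner.mode = "global"
    aln = aligner.align(seq_a, seq_b)[0]
    ia, ib = [], []
    for (a0, a1), (b0, b1) in zip(*aln.aligned):
        ia.extend(range(a0, a1))
        ib.extend(range(b0, b1))
    return xyz_a[ia], xyz_b[ib]


def align_and_rmsd(
    model_a: StructureModel,
    model_b: StructureModel,
    chain_a: str,
    chain_b: str,
    *,
    cycles: int = 5,
    reject_cutoff: float = 2.0,
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
) -> SuperpositionResult:
    """Sequence-aligned Cα superposition with iterative outlier rejection.

    Residues are paired by global sequence alignment, superposed by the
    Kabsch algorithm, then refined for up to ``cycles`` rounds, each
    removing pairs whose post-fit deviation exceeds ``reject_cutoff`` Å and
    refitting — emulating the refinement loop of molecular-graphics
    alignment tools.
    """
    ta = model_a.ca_trace(chain_a)
    tb = model_b.ca_trace(chain_b)
    if len(ta[0]) == 0 or len(tb[0]) == 0:
        raise ValueError("chain has no Cα atoms")
    A, B = _pair_ca_by_alignment(ta, tb, gap_open=gap_open, gap_extend=gap_extend)
    n_start = A.shape[0]
    keep = np.ones(n_start, dtype=bool)
    sup = kabsch_superpose(A, B)
    for _ in range(cycles):
        moved = sup.apply(B[keep])
        dev = np.linalg.norm(moved - A[keep], axis=1)
        bad = dev > reject_cutoff
        if not bad.any():
            break
        idx = np.flatnonzero(keep)
        keep[idx[bad]] = False
        if keep.sum() < 3:
            raise ValueError("fewer than 3 Cα pairs survive outlier rejection")
        sup = kabsch_superpose(A[keep], B[keep])
    return SuperpositionResult(
        rotation=sup.rotation,
        translation=sup.translation,
        rmsd=sup.rmsd,
        n_pairs=int(keep.sum()),
        rejected_pairs=int(n_start - keep.sum()),
    )


# -- per-region statistics ---------------------------------------------------


def region_bfactor_mean(
    model: StructureModel,
    chain: str,
    first_res: int | None = None,
    last_res: int | None = None,
    selection: Literal["all_atoms", "main_chain"] = "all_atoms",
) -> float:
    """Mean isotropic B-factor (Å²) over an inclusive residue range.

    ``main_chain`` restricts to backbone atoms N, CA, C, O.
    """
    names = MAIN_CHAIN_ATOMS if selection == "main_chain" else None
    df = model.select(chain=chain, first_res=first_res, last_res=last_res, atom_names=names)
    if df.empty:
        raise ValueError(
            f"no atoms in chain {chain} residues {first_res}-{last_res} ({selection})"
        )
    return float(df["b"].mean())


def _resolve_selector(model: StructureModel, selector: str) -> pd.Series:
    """Resolve "chain:resnum[:atom]" to exactly one atom row."""
    parts = selector.split(":")
    if len(parts) not in (2, 3):
        raise SelectorError(f"selector {selector!r} must be chain:resnum[:atom]")
    chain, resnum = parts[0], int(parts[1])
    atoms = [parts[2]] if len(parts) == 3 else None
    df = model.select(chain=chain, first_res=resnum, last_res=resnum, atom_names=atoms,
                      include_het=True)
    if len(df) == 0:
        raise SelectorError(f"selector {selector!r} matches no atom")
    if len(df) > 1:
        raise SelectorError(f"selector {selector!r} matches {len(df)} atoms; add an atom name")
    return df.iloc[0]


def atom_distance(
    model_a: StructureModel,
    selector_a: str,
    selector_b: str,
    model_b: StructureModel | None = None,
    post_superposition: SuperpositionResult | None = None,
) -> float:
    """Euclidean distance (Å) between two single-atom selections.

    When two models are given, ``post_superposition`` (if supplied) is
    applied to the second model's atom before measuring, so distances
    between structures are taken in the frame of the first.
    """
    row_a = _resolve_selector(model_a, selector_a)
    row_b = _resolve_selector(model_b if model_b is not None else model_a, selector_b)
    pa = row_a[["x", "y", "z"]].to_numpy(dtype=float)
    pb = row_b[["x", "y", "z"]].to_numpy(dtype=float)
    if post_superposition is not None:
        pb = post_superposition.apply(pb[None, :])[0]
    return float(np.linalg.norm(pa - pb))


# -- solvent-accessible surface area ----------------------------------------


def _sphere_points(n: int) -> np.ndarray:
    """Quasi-uniform unit-sphere points (golden-spiral lattice)."""
    i = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5.0**0.5) * i
    return np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )


def sasa(
    model: StructureModel | pd.DataFrame,
    probe_radius: float = 1.4,
    n_sphere_points: int = 960,
    include_het: bool = False,
) -> np.ndarray:
    """Per-atom solvent-accessible surface area (Å²), Shrake-Rupley.

    Each atom's accessible sphere (radius = vdW + probe) is sampled with a
    golden-spiral point lattice; a point is accessible if it lies outside
    every neighbour's accessible sphere. Returns areas aligned with the
    atom table used (polymer atoms by default).
    """
    if isinstance(model, StructureModel):
        df = model.atoms if include_het else model.polymer()
    else:
        df = model
    elements = df["element"].to_numpy()
    try:
        radii = np.array([VDW_RADII[e] for e in elements], dtype=float)
    except KeyError as err:
        raise ValueError(f"no van der Waals radius for element {err.args[0]!r}") from err
    xyz = df[["x", "y", "z"]].to_numpy(dtype=float)
    R = radii + probe_radius
    pts = _sphere_points(n_sphere_points)
    n_atoms = xyz.shape[0]
    areas = np.zeros(n_atoms)
    if n_atoms == 0:
        return areas
    tree = cKDTree(xyz)
    max_reach = 2.0 * R.max()
    neighbours = tree.query_ball_tree(tree, r=max_reach)
    for i in range(n_atoms):
        nbr = [j for j in neighbours[i] if j != i]
        test = xyz[i] + R[i] * pts
        if nbr:
            nxyz = xyz[nbr]
            nR = R[np.asarray(nbr)]
            # a test point is buried if inside any neighbour's expanded sphere
            d2 = ((test[:, None, :] - nxyz[None, :, :]) ** 2).sum(axis=2)
            accessible = (d2 >= (nR**2)[None, :]).all(axis=1)
        else:
            accessible = np.ones(n_sphere_points, dtype=bool)
        areas[i] = 4.0 * np.pi * R[i] ** 2 * accessible.mean()
    return areas


@dataclass
class InterfaceStats:
    buried_area: float  # Å², averaged over the two chains
    residue_counts: dict[str, int]
    total_residues_at_interface: int
    interface_fraction: float  # of all modelled residues
    per_residue_buried: pd.DataFrame  # chain, resnum, resname, buried_area


def interface_stats(
    model: StructureModel,
    chain_a: str,
    chain_b: str,
    *,
    probe_radius: float = 1.4,
    n_sphere_points: int = 960,
    residue_area_threshold: float = 0.1,
) -> InterfaceStats:
    """Buried surface area and interface residues between two chains.

    Buried area = (SASA(A alone) + SASA(B alone) − SASA(complex)) / 2.
    A residue is at the interface when its summed per-atom buried area
    exceeds ``residue_area_threshold`` Å².
    """
    chains = set(model.polymer()["chain"])
    for c in (chain_a, chain_b):
        if c not in chains:
            raise ValueError(f"chain {c!r} not present in model")
    df = model.polymer()
    df = df[df["chain"].isin([chain_a, chain_b])].reset_index(drop=True)
    kw = dict(probe_radius=probe_radius, n_sphere_points=n_sphere_points)
    area_complex = sasa(df, **kw)
    buried = np.zeros(len(df))
    total_alone = 0.0
    for c in (chain_a, chain_b):
        mask = (df["chain"] == c).to_numpy()
        alone = sasa(df[mask], **kw)
        buried[mask] = alone - area_complex[mask]
        total_alone += alone.sum()
    buried_total = (total_alone - area_complex.sum()) / 2.0
    per_res = (
        df.assign(buried=buried)
        .groupby(["chain", "resnum", "resname"], sort=True)["buried"]
        .sum()
        .reset_index()
        .rename(columns={"buried": "buried_area"})
    )
    iface = per_res[per_res["buried_area"] > residue_area_threshold]
    counts = {c: int((iface["chain"] == c).sum()) for c in (chain_a, chain_b)}
    n_modelled = model.residue_count(chain_a) + model.residue_count(chain_b)
    total = int(len(iface))
    return InterfaceStats(
        buried_area=float(max(buried_total, 0.0)),
        residue_counts=counts,
        total_residues_at_interface=total,
        interface_fraction=total / n_modelled if n_modelled else 0.0,
        per_residue_buried=iface.reset_index(drop=True),
    )


# -- accession fetch helper --------------------------------------------------


def default_cache_dir() -> Path:
    env = os.environ.get("PADI6TOOLS_CACHE")
    if env:
        return Path(env)
    return Path.home() / ".cache" / "padi6tools"


def cached_structure_path(accession: str, cache_dir: Path | None = None) -> Path | None:
    """Return the cached file for an accession, or None if absent."""
    cache = Path(cache_dir) if cache_dir else default_cache_dir()
    for suffix in (".pdb", ".cif"):
        p = cache / f"{accession.upper()}{suffix}"
        if p.exists():
            return p
    return None


def fetch_structure(
    accession: str, cache_dir: Path | None = None, *, allow_network: bool = False
) -> Path:
    """Fetch a deposited structure by accession into the cache (opt-in).

    Network access must be explicitly enabled; without it, only an
    already-cached file is returned.
    """
    cached = cached_structure_path(accession, cache_dir)
    if cached is not None:
        return cached
    if not allow_network:
        raise FileNotFoundError(
            f"{accession}: not in cache and network fetch not enabled "
            "(pass allow_network=True or use the CLI --fetch flag)"
        )
    import urllib.request

    cache = Path(cache_dir) if cache_dir else default_cache_dir()
    cache.mkdir(parents=True, exist_ok=True)
    dest = cache / f"{accession.upper()}.cif"
    url = f"https://files.rcsb.org/download/{accession.upper()}.cif"
    with urllib.request.urlopen(url, timeout=60) as resp:
        dest.write_bytes(resp.read())
    return dest


def write_pdb(model: StructureModel, path: str | Path) -> None:
    """Write the atom table as minimal PDB text."""
    lines = []
    serial = 0
    for row in model.atoms.itertuples():
        serial += 1
        record = "HETATM" if (row.het or row.water) else "ATOM  "
        name = row.atom if len(row.atom) == 4 else f" {row.atom:<3s}"
        lines.append(
            f"{record}{serial:5d} {name:<4s}{'':1s}{row.resname:<3s} {row.chain:1s}"
            f"{row.resnum:4d}{row.icode or '':1s}   "
            f"{row.x:8.3f}{row.y:8.3f}{row.z:8.3f}{row.occ:6.2f}{row.b:6.2f}"
            f"          {row.element:>2s}"
        )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")
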