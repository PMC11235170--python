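"""Structure and sequence statistics for tandem RRM core comparison.

Implements the structural side of the domain-comparison analysis: per-residue
solvent-accessible surface area (Shrake-Rupley), selection of the lowest-ASA
structural core, nearest-side-chain packing distances, Kabsch superposition /
Cα RMSD between the two domains, and global sequence alignment with identity
and positive-identity statistics.

Residue numbering is the author (PDB) numbering throughout; domain intervals
are inclusive and 1-based, e.g. RRM1 core 11-90 and RRM2 core 102-183 of
hnRNP A1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .errors import (
    ConfigurationError,
    EmptyInputError,
    FormatError,
    InputError,
)

__all__ = [
    "StructureModel",
    "DomainDefinition",
    "ASATable",
    "CoreSet",
    "PackingResult",
    "AlignmentStats",
    "read_structure",
    "write_pdb",
    "compute_residue_asa",
    "select_core_residues",
    "core_packing_distance",
    "superpose_kabsch",
    "domain_rmsd",
    "align_sequences",
]

# Bondi van der Waals radii (Å); the table shipped with the package.
VDW_RADII = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "SE": 1.90,
}
DEFAULT_VDW = 1.70

BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


@dataclass
class StructureModel:
    """Atomic coordinates with chain/residue/atom identity.

    Parallel-array layout: ``coords`` is an (N, 3) float array in Å and the
    identity fields are length-N sequences. Only the first model of
    multi-model files and the first alternate location are retained.
    """

    chain: list[str]
    resnum: np.ndarray          # (N,) int, author numbering
    resname: list[str]          # 3-letter codes
    atomname: list[str]
    element: list[str]
    coords: np.ndarray          # (N, 3) float, Å
    source_id: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.resnum = np.asarray(self.resnum, dtype=int)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise InputError("coords must be an (N, 3) array")
        if not np.all(np.isfinite(self.coords)):
            raise InputError("coordinates must be finite")

    def __len__(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return len(self)

    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.chain:
            seen.setdefault(c)
        return list(seen)

    def select(self, mask: np.ndarray) -> "StructureModel":
        idx = np.flatnonzero(mask)
        return StructureModel(
            chain=[self.chain[i] for i in idx],
            resnum=self.resnum[idx],
            resname=[self.resname[i] for i in idx],
            atomname=[self.atomname[i] for i in idx],
            element=[self.element[i] for i in idx],
            coords=self.coords[idx],
            source_id=self.source_id,
        )

    def residue_mask(self, resnums, chain: str | None = None) -> np.ndarray:
        wanted = set(int(r) for r in resnums)
        mask = np.array([int(r) in wanted for r in self.resnum])
        if chain is not None:
            mask &= np.array([c == chain for c in self.chain])
        return mask

    def domain(self, dom: "DomainDefinition", chain: str | None = None) -> "StructureModel":
        return self.select(self.residue_mask(range(dom.start, dom.stop + 1), chain))

    def residue_numbers(self, chain: str | None = None) -> list[int]:
        """Residue numbers in order of first appearance."""
        seen: dict[int, None] = {}
        for c, r in zip(self.chain, self.resnum):
            if chain is None or c == chain:
                seen.setdefault(int(r))
        return list(seen)

    def sequence(self, chain: str | None = None) -> str:
        seq = []
        seen: set[int] = set()
        for c, r, name in zip(self.chain, self.resnum, self.resname):
            if chain is not None and c != chain:
                continue
            if int(r) not in seen:
                seen.add(int(r))
                seq.append(THREE_TO_ONE.get(name, "X"))
        return "".join(seq)

    def ca_coords(self, resnums, chain: str | None = None) -> np.ndarray:
        """Cα coordinates for the given residue numbers, in the given order."""
        lookup: dict[int, int] = {}
        for i, (c, r, a) in enumerate(zip(self.chain, self.resnum, self.atomname)):
            if a == "CA" and (chain is None or c == chain):
                lookup.setdefault(int(r), i)
        try:
            idx = [lookup[int(r)] for r in resnums]
        except KeyError as exc:
            raise InputError(f"missing CA for residue {exc.args[0]}") from exc
        return self.coords[idx]


@dataclass(frozen=True)
class DomainDefinition:
    """Inclusive 1-based residue interval in author numbering."""

    name: str
    start: int
    stop: int

    def __post_init__(self) -> None:
        if self.stop < self.start:
            raise InputError(f"empty domain range {self.start}-{self.stop}")

    @property
    def size(self) -> int:
        return self.stop - self.start + 1

    def __contains__(self, resnum: int) -> bool:
        return self.start <= resnum <= self.stop


@dataclass
class ASATable:
    """Per-residue accessible surface area in Å²."""

    asa: dict[int, float]
    probe_radius: float
    n_points: int

    def __post_init__(self) -> None:
        if any(v < -1e-9 for v in self.asa.values()):
            raise InputError("ASA values must be non-negative")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"residue": list(self.asa), "asa_A2": list(self.asa.values())}
        )


@dataclass
class CoreSet:
    """Ordered structural-core residue numbers (size k)."""

    residues: list[int]

    @property
    def k(self) -> int:
        return len(self.residues)


@dataclass
class PackingResult:
    """Nearest-side-chain distances per core residue and their mean (Å)."""

    per_residue: dict[int, float]
    mean: float
    excluded: list[int] = field(default_factory=list)

    def rounded_mean(self, ndigits: int = 1) -> float:
        # round-half-even, the Python built-in
        return round(self.mean, ndigits)


@dataclass
class AlignmentStats:
    aligned_length: int
    identity_count: int
    positive_count: int
    aligned_pairs: list[tuple[int, int]]   # 0-based positions in seq_a/seq_b
    aligned_a: str = ""
    aligned_b: str = ""
    score: float = 0.0

    @property
    def percent_identity(self) -> float:
        if self.aligned_length == 0:
            return math.nan
        return 100.0 * self.identity_count / self.aligned_length

    @property
    def percent_positives(self) -> float:
        if self.aligned_length == 0:
            return math.nan
        return 100.0 * self.positive_count / self.aligned_length


# ---------------------------------------------------------------------------
# I/O

def read_structure(
    path: str | Path,
    drop_hydrogens: bool = True,
    source_id: str | None = None,
) -> StructureModel:
    """Parse a PDB file into a :class:`StructureModel`.

    Keeps the first MODEL and the first alternate location of each atom;
    HETATM records (waters, ligands) are excluded, as are hydrogens unless
    ``drop_hydrogens`` is False.
    """
    import gemmi

    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    try:
        st = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"unparsable PDB file {path}: {exc}") from exc
    if len(st) == 0:
        raise EmptyInputError(f"{path} contains no models")
    st.setup_entities()
    model = st[0]

    chain_l: list[str] = []
    resnum_l: list[int] = []
    resname_l: list[str] = []
    atomname_l: list[str] = []
    element_l: list[str] = []
    coords_l: list[tuple[float, float, float]] = []
    for ch in model:
        for res in ch:
            if res.het_flag == "H":    # HETATM
                continue
            seen_altloc: set[str] = set()
            for atom in res:
                if atom.altloc not in ("", "\0") and atom.altloc != "A":
                    continue
                if atom.name in seen_altloc:
                    continue
                seen_altloc.add(atom.name)
                elem = atom.element.name.upper()
                if drop_hydrogens and elem in ("H", "D"):
                    continue
                chain_l.append(ch.name)
                resnum_l.append(res.seqid.num)
                resname_l.append(res.name)
                atomname_l.append(atom.name)
                element_l.append(elem)
                coords_l.append((atom.pos.x, atom.pos.y, atom.pos.z))
    if not coords_l:
        raise EmptyInputError(f"{path} contains no ATOM records")
    return StructureModel(
        chain=chain_l,
        resnum=np.array(resnum_l),
        resname=resname_l,
        atomname=atomname_l,
        element=element_l,
        coords=np.array(coords_l),
        source_id=source_id or path.stem,
    )


def write_pdb(model: StructureModel, path: str | Path) -> None:
    """Write a StructureModel as minimal ATOM records (one chain per id)."""
    lines = []
    for i in range(len(model)):
        x, y, z = model.coords[i]
        name = model.atomname[i]
        pad = f" {name:<3s}" if len(name) < 4 else name
        lines.append(
            f"ATOM  {i + 1:>5d} {pad}{'':1s}{model.resname[i]:>3s} "
            f"{model.chain[i]:1s}{int(model.resnum[i]):>4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
            f"{model.element[i]:>2s}"
        )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Shrake-Rupley accessible surface area

def _sphere_points(n: int) -> np.ndarray:
    """Near-uniform points on the unit sphere (golden-section spiral)."""
    k = np.arange(n, dtype=float)
    phi = math.pi * (3.0 - math.sqrt(5.0)) * k
    z = 1.0 - 2.0 * (k + 0.5) / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def compute_residue_asa(
    model: StructureModel,
    probe_radius: float = 1.4,
    n_points: int = 960,
) -> ASATable:
    """Per-residue solvent-accessible surface area by sphere sampling.

    Each atom's solvent-accessible sphere (vdW radius + probe) is sampled at
    ``n_points`` near-uniform points; points falling inside any neighbouring
    atom's accessible sphere are occluded. Atom areas are summed per residue.
    """
    if len(model) == 0:
        raise EmptyInputError("empty structure")
    if probe_radius <= 0:
        raise ConfigurationError("probe radius must be positive")
    if n_points < 20:
        raise ConfigurationError("n_points < 20 gives meaningless sampling")

    radii = np.array(
        [VDW_RADII.get(e, DEFAULT_VDW) for e in model.element]
    ) + probe_radius
    coords = model.coords
    sphere = _sphere_points(n_points)
    tree = cKDTree(coords)
    max_r = radii.max()

    areas = np.zeros(len(model))
    for i in range(len(model)):
        pts = coords[i] + radii[i] * sphere
        neighbours = tree.query_ball_point(coords[i], radii[i] + max_r)
        accessible = np.ones(n_points, dtype=bool)
        for j in neighbours:
            if j == i:
                continue
            d2 = np.einsum("ij,ij->i", pts - coords[j], pts - coords[j])
            accessible &= d2 > radii[j] ** 2
        areas[i] = (
            4.0 * math.pi * radii[i] ** 2 * accessible.sum() / n_points
        )

    asa: dict[int, float] = {}
    for r, a in zip(model.resnum, areas):
        asa[int(r)] = asa.get(int(r), 0.0) + float(a)
    return ASATable(asa=asa, probe_radius=probe_radius, n_points=n_points)


def select_core_residues(
    asa: ASATable, domain: DomainDefinition, k: int = 10
) -> CoreSet:
    """The k residues of the domain with smallest ASA (ties: lower number)."""
    if k <= 0:
        raise ConfigurationError("k must be positive")
    members = [r for r in asa.asa if r in domain]
    if k > len(members):
        raise ConfigurationError(
            f"k={k} exceeds the {len(members)} residues present in {domain.name}"
        )
    ranked = sorted(members, key=lambda r: (asa.asa[r], r))
    return CoreSet(residues=sorted(ranked[:k]))


# ---------------------------------------------------------------------------
# Core packing

def core_packing_distance(
    model: StructureModel,
    core: CoreSet,
    gly_policy: str = "ca_surrogate",
    statistic: str = "per_residue",
    chain: str | None = None,
) -> PackingResult:
    """Nearest side-chain heavy-atom distances among structural-core residues.

    For each core residue the minimum distance between any of its side-chain
    heavy atoms and any side-chain heavy atom of the *other* core residues is
    taken; the reported mean is the arithmetic mean over residues
    (``statistic="pairwise"`` averages each unordered pair's nearest-atom
    distance instead). A residue without side-chain heavy atoms (glycine
    being the canonical case) uses its Cα as surrogate under the default
    policy; under ``gly_policy="exclude"`` it is dropped with a warning.
    """
    import warnings

    if core.k < 2:
        raise InputError("need at least two core residues")
    if statistic not in ("per_residue", "pairwise"):
        raise ConfigurationError(f"unknown statistic {statistic!r}")

    side_atoms: dict[int, list[int]] = {r: [] for r in core.residues}
    ca_index: dict[int, int] = {}
    for i, (c, r, a, e) in enumerate(
        zip(model.chain, model.resnum, model.atomname, model.element)
    ):
        if chain is not None and c != chain:
            continue
        r = int(r)
        if r not in side_atoms or e in ("H", "D"):
            continue
        if a in BACKBONE_ATOMS:
            if a == "CA":
                ca_index[r] = i
            continue
        side_atoms[r].append(i)

    if gly_policy == "ca_surrogate":
        for r, idx in side_atoms.items():
            if not idx and r in ca_index:
                side_atoms[r].append(ca_index[r])

    excluded = [r for r, idx in side_atoms.items() if not idx]
    if excluded:
        warnings.warn(
            f"residues without side-chain atoms excluded from packing: {excluded}"
        )
    members = [r for r in core.residues if side_atoms[r]]
    if len(members) < 2:
        raise InputError("fewer than two core residues carry side-chain atoms")

    def nearest(r_i: int, r_j: int) -> float:
        a = model.coords[side_atoms[r_i]]
        b = model.coords[side_atoms[r_j]]
        d = np.linalg.norm(a[:, None, :] - b[None, :, :], axis=-1)
        return float(d.min())

    if statistic == "per_residue":
        per_res = {
            r: min(nearest(r, s) for s in members if s != r) for r in members
        }
        mean = float(np.mean(list(per_res.values())))
    else:
        pair_d = [
            nearest(members[i], members[j])
            for i in range(len(members))
            for j in range(i + 1, len(members))
        ]
        mean = float(np.mean(pair_d))
        per_res = {
            r: min(nearest(r, s) for s in members if s != r) for r in members
        }
    return PackingResult(per_residue=per_res, mean=mean, excluded=excluded)


# ---------------------------------------------------------------------------
# Superposition and RMSD

def superpose_kabsch(
    coords_a: np.ndarray, coords_b: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of ``coords_b`` onto ``coords_a``.

    Returns ``(rotation, translation, rmsd)`` such that
    ``coords_b @ rotation.T + translation`` best matches ``coords_a``; the
    rotation is proper (det = +1) by construction.
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise InputError("point sets must be matching (N, 3) arrays")
    if a.shape[0] < 3:
        raise InputError("need at least 3 points")
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    a0, b0 = a - ca, b - cb
    h = b0.T @ a0
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    t = ca - rot @ cb
    moved = b @ rot.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((a - moved) ** 2, axis=1))))
    return rot, t, rmsd


def domain_rmsd(
    model: StructureModel,
    dom_a: DomainDefinition,
    dom_b: DomainDefinition,
    chain: str | None = None,
    matrix: str = "BLOSUM62",
    gap_open: float = -10.0,
    gap_extend: float = -0.5,
) -> float:
    """Cα RMSD between two domains after sequence-guided pairing.

    The two domain sequences are globally aligned; Cα atoms at gapless
    alignment columns are paired and superposed by the Kabsch algorithm.
    """
    sub_a = model.domain(dom_a, chain)
    sub_b = model.domain(dom_b, chain)
    res_a = sub_a.residue_numbers()
    res_b = sub_b.residue_numbers()
    stats = align_sequences(
        sub_a.sequence(), sub_b.sequence(),
        matrix=matrix, gap_open=gap_open, gap_extend=gap_extend,
    )
    if len(stats.aligned_pairs) < 3:
        raise InputError("fewer than 3 aligned residue pairs")
    nums_a = [res_a[i] for i, _ in stats.aligned_pairs]
    nums_b = [res_b[j] for _, j in stats.aligned_pairs]
    ca_a = sub_a.ca_coords(nums_a)
    ca_b = sub_b.ca_coords(nums_b)
    _, _, rmsd = superpose_kabsch(ca_a, ca_b)
    return rmsd


# ---------------------------------------------------------------------------
# Sequence alignment

def align_sequences(
    seq_a: str,
    seq_b: str,
    matrix: str = "BLOSUM62",
    gap_open: float = -10.0,
    gap_extend: float = -0.5,
) -> AlignmentStats:
    """Global alignment with identity and positive-identity statistics.

    Needleman-Wunsch with affine gaps and free terminal gaps. A column
    counts as positive when its substitution score is > 0; percentages are
    taken over the aligned length excluding terminal-gap columns.
    """
    from Bio import Align
    from Bio.Align import substitution_matrices

    if not seq_a or not seq_b:
        raise InputError("empty sequence")
    sub = substitution_matrices.load(matrix)
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = sub
    aligner.mode = "global"
    aligner.open_internal_gap_score = gap_open
    aligner.extend_internal_gap_score = gap_extend
    aligner.end_gap_score = 0.0
    aln = aligner.align(seq_a, seq_b)[0]

    ga, gb = str(aln[0]), str(aln[1])
    # trim terminal-gap columns (an all-gap alignment leaves nothing)
    start = 0
    end = len(ga)
    while start < end and (ga[start] == "-" or gb[start] == "-"):
        start += 1
    while end > start and (ga[end - 1] == "-" or gb[end - 1] == "-"):
        end -= 1

    ident = pos = 0
    pairs: list[tuple[int, int]] = []
    ia = ga[:start].replace("-", "")
    ib = gb[:start].replace("-", "")
    pos_a, pos_b = len(ia), len(ib)
    for col in range(start, end):
        x, y = ga[col], gb[col]
        if x != "-" and y != "-":
            pairs.append((pos_a, pos_b))
            if x == y:
                ident += 1
            if sub[x, y] > 0:
                pos += 1
        if x != "-":
            pos_a += 1
        if y != "-":
            pos_b += 1
    return AlignmentStats(
        aligned_length=end - start,
        identity_count=ident,
        positive_count=pos,
        aligned_pairs=pairs,
        aligned_a=ga,
        aligned_b=gb,
        score=float(aln.score),
    )
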