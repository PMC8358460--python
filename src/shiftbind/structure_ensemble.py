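"""Multi-model coordinate statistics for disulfide-rich peptide ensembles.

Provides PDB ensemble I/O (via gemmi), Kabsch least-squares superposition,
iterative RMSD-to-mean-coordinate statistics of NMR ensembles, geometric
disulfide detection (mutual-nearest SG contacts), single-linkage surface
patch identification, and restraint bookkeeping in the conventional
intra/sequential/medium/long-range bins.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .peptide_chem import DisulfideTopology

__all__ = [
    "AtomRecord",
    "Model",
    "ModelEnsemble",
    "RestraintRecord",
    "RestraintStats",
    "SurfacePatch",
    "read_pdb_ensemble",
    "superpose",
    "mean_coordinate_rmsd",
    "detect_disulfides",
    "classify_restraints",
    "find_patches",
    "read_restraint_tsv",
    "write_restraint_tsv",
]

BACKBONE_ATOMS = ("N", "CA", "C", "O")
#: Representative side-chain atoms of the basic class.
BASIC_REPRESENTATIVE = {"ARG": "CZ", "LYS": "NZ"}
#: Default hydrophobic class (side-chain centroid representative).
HYDROPHOBIC_CLASS = ("PHE", "THR", "HIS")

_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS", "Q": "GLN",
    "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE", "L": "LEU", "K": "LYS",
    "M": "MET", "F": "PHE", "P": "PRO", "S": "SER", "T": "THR", "W": "TRP",
    "Y": "TYR", "V": "VAL",
}
THREE_LETTER = _THREE


@dataclass(frozen=True)
class AtomRecord:
    model_index: int
    chain: str
    res_num: int
    res_name: str
    atom_name: str
    xyz: tuple[float, float, float]


@dataclass
class Model:
    """One set of coordinates, indexed by (residue number, atom name)."""

    atoms: dict[tuple[int, str], AtomRecord]

    def coords(self, keys) -> np.ndarray:
        return np.array([self.atoms[k].xyz for k in keys])

    def residues(self) -> list[int]:
        return sorted({r for r, _ in self.atoms})

    def res_name(self, res_num: int) -> str:
        for (r, _), a in self.atoms.items():
            if r == res_num:
                return a.res_name
        raise KeyError(res_num)


@dataclass
class ModelEnsemble:
    """Models sharing identical residue numbering and atom-name sets."""

    models: list[Model]

    def __post_init__(self) -> None:
        keys0 = set(self.models[0].atoms)
        for i, m in enumerate(self.models[1:], start=2):
            diff = keys0 ^ set(m.atoms)
            if diff:
                sample = sorted(diff)[:5]
                raise ValueError(
                    f"model {i} atom set differs from model 1 at {len(diff)} "
                    f"positions, e.g. {sample}"
                )

    def __len__(self) -> int:
        return len(self.models)

    def atom_keys(self, selection=None) -> list[tuple[int, str]]:
        keys = sorted(self.models[0].atoms)
        if selection is not None:
            keys = [k for k in keys if selection(self.models[0].atoms[k])]
        return keys


def backbone_selection(atom: AtomRecord) -> bool:
    return atom.atom_name in BACKBONE_ATOMS


def heavy_selection(atom: AtomRecord) -> bool:
    return not atom.atom_name.startswith("H")


def residue_range_selection(lo_hi_pairs, base=heavy_selection):
    ranges = tuple(lo_hi_pairs)

    def pred(atom: AtomRecord) -> bool:
        return base(atom) and any(lo <= atom.res_num <= hi for lo, hi in ranges)

    return pred


def read_pdb_ensemble(path) -> ModelEnsemble:
    """Read a (possibly multi-model) PDB file into an ensemble.

    Hydrogens are kept; single-model files yield a 1-model ensemble.  Models
    with inconsistent atom sets are rejected with the discrepancies listed.
    """
    import gemmi

    st = gemmi.read_structure(str(path))
    st.setup_entities()
    models = []
    for mi, model in enumerate(st, start=1):
        atoms: dict[tuple[int, str], AtomRecord] = {}
        for chain in model:
            for res in chain:
                for atom in res:
                    atoms[(res.seqid.num, atom.name)] = AtomRecord(
                        model_index=mi,
                        chain=chain.name,
                        res_num=res.seqid.num,
                        res_name=res.name,
                        atom_name=atom.name,
                        xyz=(atom.pos.x, atom.pos.y, atom.pos.z),
                    )
        models.append(Model(atoms))
    if not models:
        raise ValueError(f"no models found in {path}")
    return ModelEnsemble(models)


def _kabsch(mobile: np.ndarray, reference: np.ndarray):
    """Least-squares proper rotation + translation mapping mobile onto reference."""
    cm, cr = mobile.mean(axis=0), reference.mean(axis=0)
    h = (mobile - cm).T @ (reference - cr)
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    trans = cr - rot @ cm
    return rot, trans


def superpose(mobile_xyz: np.ndarray, reference_xyz: np.ndarray):
    """Optimal rigid superposition (Kabsch) of paired coordinate arrays.

    Returns ``(rotation 3x3, translation 3, rmsd)`` with det(rotation)=+1.
    Requires >= 3 non-collinear atom pairs.
    """
    mobile_xyz = np.asarray(mobile_xyz, dtype=float)
    reference_xyz = np.asarray(reference_xyz, dtype=float)
    if mobile_xyz.shape != reference_xyz.shape or mobile_xyz.ndim != 2:
        raise ValueError("coordinate arrays must be matching (n, 3)")
    n = mobile_xyz.shape[0]
    if n < 3:
        raise ValueError("need at least 3 atom pairs")
    centered = mobile_xyz - mobile_xyz.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-8) < 2:
        raise ValueError("degenerate (collinear) selection")
    rot, trans = _kabsch(mobile_xyz, reference_xyz)
    moved = mobile_xyz @ rot.T + trans
    rmsd = float(np.sqrt(((moved - reference_xyz) ** 2).sum(axis=1).mean()))
    return rot, trans, rmsd


def mean_coordinate_rmsd(
    ensemble: ModelEnsemble,
    selection=backbone_selection,
    tol: float = 1e-6,
    max_iter: int = 100,
):
    """Mean +/- sd of per-model RMSDs to the converged mean coordinates.

    All models are iteratively superposed onto the running mean over the
    selection (initial reference: model 1) until the mean shifts by less
    than ``tol`` angstrom.  The sd is the sample standard deviation (n-1).
    """
    if len(ensemble) < 2:
        raise ValueError("ensemble must contain at least 2 models")
    keys = ensemble.atom_keys(selection)
    if len(keys) < 3:
        raise ValueError("selection leaves fewer than 3 atoms")
    coords = np.array([m.coords(keys) for m in ensemble.models])
    mean = coords[0].copy()
    for _ in range(max_iter):
        fitted = []
        for xyz in coords:
            rot, trans, _ = superpose(xyz, mean)
            fitted.append(xyz @ rot.T + trans)
        fitted = np.array(fitted)
        new_mean = fitted.mean(axis=0)
        shift = float(np.abs(new_mean - mean).max())
        mean = new_mean
        coords = fitted
        if shift < tol:
            break
    else:
        raise RuntimeError(
            f"mean coordinates did not converge in {max_iter} iterations "
            f"(last shift {shift:.3e} A)"
        )
    rmsds = np.sqrt(((coords - mean) ** 2).sum(axis=2).mean(axis=1))
    return float(rmsds.mean()), float(rmsds.std(ddof=1))


def detect_disulfides(model: Model, sg_cutoff: float = 2.5) -> DisulfideTopology:
    """Disulfide pairs as mutual-nearest SG-SG contacts below ``sg_cutoff``.

    The covalent S-S bond is ~2.05 A; the default cutoff leaves margin for
    coordinate noise.  An SG with two sub-cutoff partners, neither mutually
    nearest, raises instead of being silently assigned.  The framework
    ordinal of each cysteine is its rank among the model's cysteines.
    """
    sgs = {
        r: np.array(a.xyz)
        for (r, name), a in model.atoms.items()
        if name == "SG" and a.res_name == "CYS"
    }
    resnums = sorted(sgs)
    if not resnums:
        return DisulfideTopology(pairs=(), framework="")
    nearest: dict[int, tuple[float, int]] = {}
    for i, ri in enumerate(resnums):
        best = None
        for rj in resnums:
            if rj == ri:
                continue
            d = float(np.linalg.norm(sgs[ri] - sgs[rj]))
            if best is None or d < best[0]:
                best = (d, rj)
        if best is not None:
            nearest[ri] = best
    pairs = []
    paired: set[int] = set()
    for ri in resnums:
        if ri in paired or ri not in nearest:
            continue
        d, rj = nearest[ri]
        if d > sg_cutoff:
            continue
        if nearest[rj][1] == ri:
            pairs.append((min(ri, rj), max(ri, rj)))
            paired.update((ri, rj))
        else:
            partners = [
                rk
                for rk in resnums
                if rk != ri and np.linalg.norm(sgs[ri] - sgs[rk]) <= sg_cutoff
            ]
            raise ValueError(
                f"ambiguous disulfide at Cys{ri}: sub-cutoff partners "
                f"{partners} but no mutual nearest match"
            )
    rank = {r: i + 1 for i, r in enumerate(resnums)}
    pairs.sort(key=lambda p: rank[p[0]])
    framework = ",".join(f"{rank[i]}-{rank[j]}" for i, j in pairs)
    return DisulfideTopology(pairs=tuple(pairs), framework=framework)


@dataclass(frozen=True)
class RestraintRecord:
    """A residue/atom-level restraint with distance bounds, for bookkeeping."""

    res_i: int
    res_j: int
    atom_i: str = ""
    atom_j: str = ""
    lower: float = 0.0
    upper: float = 0.0
    category: str = "distance"  # distance | disulfide | dihedral

    def __post_init__(self) -> None:
        if not (0 <= self.lower <= self.upper):
            raise ValueError("bounds must satisfy 0 <= lower <= upper")
        if self.category not in ("distance", "disulfide", "dihedral"):
            raise ValueError(f"unknown category {self.category!r}")


@dataclass(frozen=True)
class RestraintStats:
    total_distance: int
    intra: int
    sequential: int
    medium: int
    long: int
    disulfide: int
    dihedral: int
    restraints_per_residue: float


def classify_restraints(
    restraints: "list[RestraintRecord]", seq_length: int
) -> RestraintStats:
    """Bin distance restraints by sequence separation |i-j|.

    intra =0, sequential =1, medium 2-4, long >=5; the per-residue figure
    counts distance + disulfide + dihedral restraints over the sequence
    length.
    """
    counts = {"intra": 0, "sequential": 0, "medium": 0, "long": 0}
    n_ss = n_dih = 0
    for r in restraints:
        if not (1 <= r.res_i <= seq_length and 1 <= r.res_j <= seq_length):
            raise ValueError(
                f"restraint {r.res_i}-{r.res_j} outside 1..{seq_length}"
            )
        if r.category == "disulfide":
            n_ss += 1
            continue
        if r.category == "dihedral":
            n_dih += 1
            continue
        sep = abs(r.res_i - r.res_j)
        if sep == 0:
            counts["intra"] += 1
        elif sep == 1:
            counts["sequential"] += 1
        elif sep < 5:
            counts["medium"] += 1
        else:
            counts["long"] += 1
    total = sum(counts.values())
    return RestraintStats(
        total_distance=total,
        intra=counts["intra"],
        sequential=counts["sequential"],
        medium=counts["medium"],
        long=counts["long"],
        disulfide=n_ss,
        dihedral=n_dih,
        restraints_per_residue=(total + n_ss + n_dih) / seq_length,
    )


@dataclass(frozen=True)
class SurfacePatch:
    kind: str  # basic | hydrophobic
    members: tuple[int, ...]
    centroid: tuple[float, float, float]


def _representative_points(model: Model, kind: str, hydrophobic_class):
    """Per-residue representative point of the requested surface class."""
    import warnings

    points: dict[int, np.ndarray] = {}
    for res in model.residues():
        name = model.res_name(res)
        if kind == "basic":
            rep = BASIC_REPRESENTATIVE.get(name)
            if rep is None:
                continue
            atom = model.atoms.get((res, rep))
            if atom is None:
                warnings.warn(f"residue {name}{res} missing {rep}; skipped")
                continue
            points[res] = np.array(atom.xyz)
        elif kind == "hydrophobic":
            if name not in hydrophobic_class:
                continue
            side = [
                np.array(a.xyz)
                for (r, an), a in model.atoms.items()
                if r == res and an not in BACKBONE_ATOMS and not an.startswith("H")
            ]
            if not side:
                warnings.warn(f"residue {name}{res} has no side-chain atoms; skipped")
                continue
            points[res] = np.mean(side, axis=0)
        else:
            raise ValueError(f"unknown patch kind {kind!r}")
    return points


def find_patches(
    model: Model,
    kind: str,
    link_cutoff: float = 10.0,
    hydrophobic_class=HYDROPHOBIC_CLASS,
) -> list[SurfacePatch]:
    """Single-linkage clusters of class representative points.

    Clusters of size >= 2 within ``link_cutoff`` (A) are reported as patches,
    ordered by first residue; membership is invariant to input order.
    """
    points = _representative_points(model, kind, hydrophobic_class)
    residues = sorted(points)
    parent = {r: r for r in residues}

    def find(r):
        while parent[r] != r:
            parent[r] = parent[parent[r]]
            r = parent[r]
        return r

    for i, ri in enumerate(residues):
        for rj in residues[i + 1:]:
            if np.linalg.norm(points[ri] - points[rj]) <= link_cutoff:
                parent[find(ri)] = find(rj)
    clusters: dict[int, list[int]] = {}
    for r in residues:
        clusters.setdefault(find(r), []).append(r)
    patches = []
    for members in clusters.values():
        if len(members) < 2:
            continue
        members = tuple(sorted(members))
        centroid = np.mean([points[r] for r in members], axis=0)
        patches.append(SurfacePatch(kind, members, tuple(float(c) for c in centroid)))
    patches.sort(key=lambda p: p.members[0])
    return patches


# ---------------------------------------------------------------------------
# Restraint list I/O (TSV: i, j, atom_i, atom_j, lower, upper, category)

def read_restraint_tsv(path) -> list[RestraintRecord]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            i, j, ai, aj, lo, hi, cat = line.split("\t")
            out.append(
                RestraintRecord(int(i), int(j), ai, aj, float(lo), float(hi), cat)
            )
    return out


def write_restraint_tsv(restraints, path) -> None:
    with open(path, "w") as fh:
        fh.write("# res_i\tres_j\tatom_i\tatom_j\tlower\tupper\tcategory\n")
        for r in restraints:
            fh.write(
                f"{r.res_i}\t{r.res_j}\t{r.atom_i}\t{r.atom_j}\t"
                f"{r.lower:.2f}\t{r.upper:.2f}\t{r.category}\n"
            )


def stats_to_json(stats: RestraintStats) -> str:
    return json.dumps(stats.__dict__, indent=2)
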