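"""Seeded generators for every input the pipeline consumes.

Three generators with known ground truth:

* HSQC titration series under fast exchange — peaks move by
  ``f_bound * ddelta_max`` and lose intensity through an exchange-broadening
  factor, over the study ladder (55 uM peptide; receptor 0/21/34/45/57/95/
  125 uM) with optional competitor-displacement points;
* ITC thermograms for the study injection schedule with Gaussian heat noise;
* toy multi-model coordinate ensembles of a 36-residue ClTx-like peptide
  realizing the native disulfide topology (framework 1-4,2-6,3-7,5-8), two
  basic surface clusters ({14,15,23}, {25,27,36}) and a hydrophobic cluster
  ({6,7,8,10}), with per-model jitter and random rigid motions.

All generators are pure functions of (parameters, seed); a manifest records
both so regeneration is byte-identical.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .binding_equilibria import (
    BindingParameters,
    bound_fraction_1to1,
    competitive_equilibrium,
)
from .itc_model import InjectionSchedule, Thermogram, simulate_thermogram
from .peptide_chem import CLTX_SEQUENCE
from .structure_ensemble import THREE_LETTER
from .titration_csp import Peak, PeakList, TitrationSeries, write_peak_list

__all__ = [
    "TitrationGroundTruth",
    "FixtureManifest",
    "default_ground_truth",
    "make_titration_series",
    "make_titration_fixture",
    "make_thermogram_fixture",
    "make_toy_ensemble",
    "DEFAULT_LADDER",
    "SHIFT_INTERFACE",
    "INTENSITY_INTERFACE",
]

#: Receptor concentration ladder of the study (molar); reference first.
DEFAULT_LADDER = (0.0, 21e-6, 34e-6, 45e-6, 57e-6, 95e-6, 125e-6)
#: Peptide (observed species) concentration (molar).
DEFAULT_OBSERVED = 55e-6
#: Residues whose chemical shifts move on receptor binding.
SHIFT_INTERFACE = (2, 20, 21, 23, 25, 26, 28, 29, 34)
#: Residues whose peaks broaden (intensity loss) on receptor binding.
INTENSITY_INTERFACE = (2, 25, 26, 27, 28, 35, 36)
#: ClTx binds NRP1-b1 with Kd 143.3 uM; the EG00229 competitor with 7.9 uM.
DEFAULT_KD = 143.3e-6
DEFAULT_KD_COMPETITOR = 7.9e-6


@dataclass(frozen=True)
class TitrationGroundTruth:
    """Generating parameters of a synthetic titration.

    ``ddelta_max`` maps residue -> (ddH_max, ddN_max) in ppm at full
    saturation; ``broadening`` maps residue -> beta in [0, 1], the fraction
    of intensity *retained* at full occupancy (1 = no broadening).
    """

    kd: float = DEFAULT_KD
    ddelta_max: dict[int, tuple[float, float]] = field(default_factory=dict)
    broadening: dict[int, float] = field(default_factory=dict)
    shift_interface: tuple[int, ...] = SHIFT_INTERFACE
    intensity_interface: tuple[int, ...] = INTENSITY_INTERFACE
    shift_noise_ppm: float = 0.002
    intensity_noise_frac: float = 0.02
    seed: int = 42

    def __post_init__(self) -> None:
        for b in self.broadening.values():
            if not 0.0 <= b <= 1.0:
                raise ValueError("broadening factors must lie in [0, 1]")
        for dh, dn in self.ddelta_max.values():
            if dh < 0 or dn < 0:
                raise ValueError("ddelta_max components must be non-negative")


@dataclass(frozen=True)
class FixtureManifest:
    generator: str
    seed: int
    parameters: dict
    files: tuple[str, ...]


def _non_proline_residues(sequence: str = CLTX_SEQUENCE) -> list[int]:
    return [i + 1 for i, a in enumerate(sequence) if a != "P"]


def default_ground_truth(seed: int = 42) -> TitrationGroundTruth:
    """Study-condition ground truth for the default fixture.

    Interface residues get saturation shifts of 0.25-0.45 ppm (combined
    scale) drawn reproducibly from the seed; intensity-interface residues
    retain only 15% of their intensity at full occupancy.  Off-interface
    residues move only by measurement noise.
    """
    rng = np.random.default_rng(seed)
    ddmax = {}
    for r in SHIFT_INTERFACE:
        combined = rng.uniform(0.25, 0.45)
        dh = combined * rng.uniform(0.6, 0.9)
        dn = math.sqrt(max(combined**2 - dh**2, 0.0)) / 0.2
        ddmax[r] = (dh, dn)
    broadening = {r: 0.15 for r in INTENSITY_INTERFACE}
    return TitrationGroundTruth(
        ddelta_max=ddmax, broadening=broadening, seed=seed
    )


def make_titration_series(
    truth: TitrationGroundTruth | None = None,
    ladder=DEFAULT_LADDER,
    observed_conc: float = DEFAULT_OBSERVED,
    competitor_points=((125e-6, 413e-6),),
    kd_competitor: float = DEFAULT_KD_COMPETITOR,
    sequence: str = CLTX_SEQUENCE,
    drop_threshold: float = 0.05,
) -> TitrationSeries:
    """Generate an in-memory fast-exchange titration series.

    Per point and residue: ``delta_obs = delta_free + f_bound * ddelta_max``
    with additive Gaussian shift noise, and
    ``I = I0 * (1 - f_bound * (1 - beta))`` with multiplicative log-normal
    noise; peaks below ``drop_threshold`` of the reference intensity are
    omitted (vanished-peak emulation).  ``competitor_points`` are
    (receptor_conc, competitor_conc) pairs appended after the ladder.
    """
    if truth is None:
        truth = default_ground_truth()
    if list(ladder) != sorted(ladder) or ladder[0] != 0:
        raise ValueError("ladder must be non-decreasing and start at 0")
    rng = np.random.default_rng(truth.seed)
    residues = _non_proline_residues(sequence)

    # Reproducible free-state spectrum.
    free = {
        r: Peak(
            dH=float(rng.uniform(7.5, 9.5)),
            dN=float(rng.uniform(105.0, 130.0)),
            intensity=float(rng.uniform(0.8e5, 1.2e5)),
        )
        for r in residues
    }

    def build_point(p_tot: float, b_tot: float) -> PeakList:
        if b_tot > 0:
            st = competitive_equilibrium(
                p_tot, observed_conc, b_tot, truth.kd, kd_competitor
            )
            f_bound = st.fraction_a_bound
        elif p_tot > 0:
            f_bound = bound_fraction_1to1(p_tot, observed_conc, truth.kd)
        else:
            f_bound = 0.0
        peaks = {}
        for r in residues:
            dh_max, dn_max = truth.ddelta_max.get(r, (0.0, 0.0))
            beta = truth.broadening.get(r, 1.0)
            dh = free[r].dH + f_bound * dh_max + rng.normal(0, truth.shift_noise_ppm)
            dn = free[r].dN + f_bound * dn_max + rng.normal(
                0, truth.shift_noise_ppm * 5
            )
            inten = free[r].intensity * (1.0 - f_bound * (1.0 - beta))
            if truth.intensity_noise_frac > 0:
                inten *= math.exp(rng.normal(0, truth.intensity_noise_frac))
            if inten < drop_threshold * free[r].intensity:
                continue  # peak vanished into the noise floor
            peaks[r] = Peak(float(dh), float(dn), float(inten))
        return PeakList(peaks, receptor_conc=p_tot, competitor_conc=b_tot)

    points = [
        PeakList(dict(free), receptor_conc=0.0, competitor_conc=0.0)
    ]
    points += [build_point(p, 0.0) for p in ladder[1:]]
    points += [build_point(p, b) for p, b in competitor_points]
    return TitrationSeries(observed_conc=observed_conc, points=tuple(points))


def make_titration_fixture(
    outdir,
    truth: TitrationGroundTruth | None = None,
    ladder=DEFAULT_LADDER,
    observed_conc: float = DEFAULT_OBSERVED,
    competitor_points=((125e-6, 413e-6),),
    kd_competitor: float = DEFAULT_KD_COMPETITOR,
) -> FixtureManifest:
    """Write a titration series as peak-list files plus a manifest CSV."""
    if truth is None:
        truth = default_ground_truth()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    series = make_titration_series(
        truth, ladder, observed_conc, competitor_points, kd_competitor
    )
    names = {i + 1: a for i, a in enumerate(CLTX_SEQUENCE)}
    files = []
    rows = []
    for k, point in enumerate(series.points):
        fn = f"point_{k:02d}.list"
        write_peak_list(point, outdir / fn, residue_names=names)
        files.append(fn)
        rows.append(
            {
                "filename": fn,
                "receptor_conc_uM": f"{point.receptor_conc * 1e6:.6g}",
                "competitor_conc_uM": f"{point.competitor_conc * 1e6:.6g}",
            }
        )
    with open(outdir / "manifest.csv", "w", newline="") as fh:
        writer = csv.DictWriter(
            fh, fieldnames=["filename", "receptor_conc_uM", "competitor_conc_uM"]
        )
        writer.writeheader()
        writer.writerows(rows)
    manifest = FixtureManifest(
        generator="make_titration_fixture",
        seed=truth.seed,
        parameters={
            "kd_M": truth.kd,
            "observed_conc_M": observed_conc,
            "ladder_M": list(ladder),
            "competitor_points_M": [list(cp) for cp in competitor_points],
            "kd_competitor_M": kd_competitor,
            "shift_noise_ppm": truth.shift_noise_ppm,
            "intensity_noise_frac": truth.intensity_noise_frac,
        },
        files=tuple(files + ["manifest.csv"]),
    )
    with open(outdir / "fixture.json", "w") as fh:
        json.dump(asdict(manifest), fh, indent=2, sort_keys=True)
    return manifest


def make_thermogram_fixture(
    outdir,
    params: BindingParameters,
    schedule: InjectionSchedule,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[Thermogram, FixtureManifest]:
    """Simulate a thermogram and persist it as CSV plus a manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tg = simulate_thermogram(params, schedule, noise_sd=noise_sd, seed=seed)
    fn = "thermogram.csv"
    with open(outdir / fn, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["injection_index", "volume_uL", "NDH_kcal_per_mol"])
        for i, (dv, ndh) in enumerate(zip(schedule.injection_volumes, tg.ndh), 1):
            writer.writerow([i, f"{dv * 1e6:.4f}", f"{ndh:.10g}"])
    manifest = FixtureManifest(
        generator="make_thermogram_fixture",
        seed=seed,
        parameters={
            "kd_a_M": params.kd_a,
            "dh_a_kcal_mol": params.dh_a,
            "kd_b_M": params.kd_b,
            "dh_b_kcal_mol": params.dh_b,
            "n": params.n,
            "noise_sd": noise_sd,
            "cell_volume_L": schedule.cell_volume,
            "cell_conc_M": schedule.cell_conc,
            "syringe_conc_M": schedule.syringe_conc,
            "cell_competitor_conc_M": schedule.cell_competitor_conc,
            "temperature_K": schedule.temperature,
        },
        files=(fn,),
    )
    with open(outdir / "fixture.json", "w") as fh:
        json.dump(asdict(manifest), fh, indent=2, sort_keys=True)
    return tg, manifest


def read_thermogram_csv(path) -> Thermogram:
    """Read a thermogram CSV written by :func:`make_thermogram_fixture`."""
    ndh = []
    with open(path) as fh:
        for row in csv.DictReader(fh):
            ndh.append(float(row["NDH_kcal_per_mol"]))
    return Thermogram(ndh=tuple(ndh))


# ---------------------------------------------------------------------------
# Toy coordinate ensembles

# Disulfide pair anchors (SG pairs straddle these points at 2.05 A).
_SS_PAIRS = ((2, 19), (5, 28), (16, 33), (20, 35))
_BASIC_CLUSTERS = ({14: "CZ", 15: "NZ", 23: "NZ"}, {25: "CZ", 27: "NZ", 36: "CZ"})
_HYDROPHOBIC = (6, 7, 8, 10)


def _base_coordinates(sequence: str = CLTX_SEQUENCE):
    """Hand-built reference geometry realizing the tested surface features.

    Backbone atoms run along a gentle helix; SG pairs, basic cluster
    representatives and hydrophobic side-chain atoms are placed at
    constructed anchor points.  The geometry is a test scaffold, not a
    physical peptide model.
    """
    atoms: dict[tuple[int, str], tuple[str, np.ndarray]] = {}
    n_res = len(sequence)
    for i in range(1, n_res + 1):
        res3 = THREE_LETTER[sequence[i - 1]]
        t = 0.6 * i
        ca = np.array([1.9 * i, 3.0 * math.sin(t), 3.0 * math.cos(t)])
        atoms[(i, "N")] = (res3, ca + np.array([-1.20, 0.80, 0.10]))
        atoms[(i, "CA")] = (res3, ca)
        atoms[(i, "C")] = (res3, ca + np.array([1.20, 0.75, -0.10]))
        atoms[(i, "O")] = (res3, ca + np.array([1.30, 1.95, -0.15]))
        if res3 != "GLY":
            atoms[(i, "CB")] = (res3, ca + np.array([0.0, -1.50, 0.4]))
    # Disulfides: each pair's SG atoms straddle an anchor, 2.05 A apart;
    # anchors 10 A apart so cross-pair SG distances stay > 6 A.
    for k, (ri, rj) in enumerate(_SS_PAIRS):
        anchor = np.array([10.0 * k + 5.0, -9.0, 7.0])
        atoms[(ri, "SG")] = ("CYS", anchor + np.array([-1.025, 0.0, 0.0]))
        atoms[(rj, "SG")] = ("CYS", anchor + np.array([1.025, 0.0, 0.0]))
    # Basic clusters: representatives within 6 A internally, clusters 40 A apart.
    centers = (np.array([5.0, 14.0, 0.0]), np.array([45.0, 14.0, 0.0]))
    offsets = (
        np.array([-2.0, 0.0, 0.0]),
        np.array([2.0, 0.0, 0.0]),
        np.array([0.0, 3.0, 0.0]),
    )
    for center, cluster in zip(centers, _BASIC_CLUSTERS):
        for (res, rep), off in zip(cluster.items(), offsets):
            res3 = THREE_LETTER[sequence[res - 1]]
            atoms[(res, rep)] = (res3, center + off)
    # Hydrophobic cluster: override CB of the class members near one point.
    hp_center = np.array([25.0, 18.0, 6.0])
    hp_offsets = (
        np.array([-1.5, 0.0, 0.0]),
        np.array([1.5, 0.0, 0.0]),
        np.array([0.0, 1.5, 1.0]),
        np.array([0.0, -1.5, 1.0]),
    )
    for res, off in zip(_HYDROPHOBIC, hp_offsets):
        res3 = THREE_LETTER[sequence[res - 1]]
        atoms[(res, "CB")] = (res3, hp_center + off)
    return atoms


def _random_rotation(rng) -> np.ndarray:
    """Uniform random proper rotation via QR of a Gaussian matrix."""
    m = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(m)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def make_toy_ensemble(
    path,
    seed: int = 1,
    n_models: int = 3,
    perturbation_sd: float = 0.05,
    apply_rigid_motions: bool = True,
) -> FixtureManifest:
    """Write a multi-model PDB of the toy ClTx-like peptide.

    Each model is the base geometry plus isotropic Gaussian jitter of
    ``perturbation_sd`` (A) and, optionally, a random rigid motion.
    """
    if n_models < 1:
        raise ValueError("n_models must be >= 1")
    rng = np.random.default_rng(seed)
    base = _base_coordinates()
    keys = sorted(base)
    path = Path(path)
    lines = []
    for mi in range(1, n_models + 1):
        rot = _random_rotation(rng) if apply_rigid_motions else np.eye(3)
        trans = rng.uniform(-20, 20, size=3) if apply_rigid_motions else np.zeros(3)
        lines.append(f"MODEL     {mi:4d}")
        serial = 1
        for res_num, atom_name in keys:
            res3, xyz = base[(res_num, atom_name)]
            p = rot @ (xyz + rng.normal(0, perturbation_sd, size=3)) + trans
            element = atom_name[0]
            # PDB fixed columns; short atom names start in column 14.
            name_field = atom_name if len(atom_name) == 4 else f" {atom_name:<3s}"
            lines.append(
                f"ATOM  {serial:5d} {name_field} {res3:>3s} A{res_num:4d}    "
                f"{p[0]:8.3f}{p[1]:8.3f}{p[2]:8.3f}{1.0:6.2f}{0.0:6.2f}"
                f"          {element:>2s}"
            )
            serial += 1
        lines.append("ENDMDL")
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")
    manifest = FixtureManifest(
        generator="make_toy_ensemble",
        seed=seed,
        parameters={
            "n_models": n_models,
            "perturbation_sd_A": perturbation_sd,
            "rigid_motions": apply_rigid_motions,
        },
        files=(path.name,),
    )
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump(asdict(manifest), fh, indent=2, sort_keys=True)
    return manifest
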