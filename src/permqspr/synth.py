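"""Synthetic-data generators and packaged fixtures.

Everything the pipeline consumes can be generated here: factorial
descriptor tables with planted sparse linear responses, correlated
descriptor blocks, and forward-simulated Franz-cell concentration series
with sampling withdrawal and measurement noise.  Each generator is a
pure function of its configuration and seed, and returns a truth record
so recovery tests are self-validating.

The module also ships two fixed fixtures: the epidermal permeation table
(fluxes and permeability coefficients of three permeants from five oily
vehicles and buffer, checksummed so it cannot silently drift) and the
SMILES structures of the study compounds.  The default HSP table is
synthetic (plausible values for running the pipeline, not measurements).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .descriptors import compute_descriptors
from .graph import MolecularGraph, parse_structure
from .hansen import HSPTriplet, hsp_distance, read_hsp_csv
from .permeation import FranzCellSeries

__all__ = [
    "StudyDesign",
    "GeneratorConfig",
    "CorrelatedBlock",
    "FIXTURE_SMILES",
    "fixture_molecules",
    "fixture_table1",
    "default_hsp",
    "generate_dataset",
    "generate_franz_series",
    "planted_factor_matrix",
    "sparse_linear_dataset",
    "flux_stderr_known_sigma",
]

_TABLE1_SHA256 = "1a3b03853dd689470b4a505444b54d7455e4d31b2d09a4646d3331ddd4d63fff"

#: Study compounds: three permeants and four oily vehicles.
#: IHD is represented by the branched-C16 isoparaffin
#: 2,2,4,4,6,8,8-heptamethylnonane.
FIXTURE_SMILES = {
    "CF": "Cn1cnc2c1c(=O)n(C)c(=O)n2C",
    "MP": "COC(=O)c1ccc(O)cc1",
    "BP": "CCCCOC(=O)c1ccc(O)cc1",
    "IPM": "CCCCCCCCCCCCCC(=O)OC(C)C",
    "OA": "CCCCCCCC/C=C\\CCCCCCCC(=O)O",
    "HD": "CCCCCCCCCCCCCCCC",
    "IHD": "CC(C)(C)CC(C)(C)CC(C)CC(C)(C)C",
}

_ROLES = {"CF": "permeant", "MP": "permeant", "BP": "permeant",
          "IPM": "vehicle", "OA": "vehicle", "HD": "vehicle", "IHD": "vehicle"}


def fixture_molecules() -> dict[str, MolecularGraph]:
    """Parsed heavy-atom graphs of the study compounds, keyed by label."""
    return {name: parse_structure(smi, label=name) for name, smi in FIXTURE_SMILES.items()}


def _data_path(name: str):
    return resources.files("permqspr.data").joinpath(name)


def fixture_table1(verify: bool = True) -> pd.DataFrame:
    """Epidermal permeation fixture: mean/sd flux (ug cm^-2 h^-1) and
    permeability coefficient (10^-2 cm h^-1) per vehicle and permeant."""
    path = _data_path("table1_epidermal.csv")
    raw = path.read_bytes()
    if verify:
        digest = hashlib.sha256(raw).hexdigest()
        if digest != _TABLE1_SHA256:
            raise RuntimeError(
                "packaged epidermal permeation table failed its checksum "
                f"({digest}); the fixture has been modified"
            )
    import io

    return pd.read_csv(io.BytesIO(raw))


def default_hsp() -> dict[str, HSPTriplet]:
    """Synthetic default HSP triplets for vehicles, membranes, permeants."""
    with resources.as_file(_data_path("hsp_defaults_synthetic.csv")) as p:
        return read_hsp_csv(p)


# ---------------------------------------------------------------------------
# factorial design
# ---------------------------------------------------------------------------

@dataclass
class StudyDesign:
    """Factorial layout: permeant x vehicle x membrane combinations."""

    permeants: tuple[str, ...] = ("CF", "MP", "BP")
    vehicles: tuple[str, ...] = ("IHD", "HD", "OA", "IPM")
    membranes: tuple[str, ...] = ("silicone", "HDPE", "PU")

    def __post_init__(self) -> None:
        for name in ("permeants", "vehicles", "membranes"):
            vals = getattr(self, name)
            if len(set(vals)) != len(vals):
                raise ValueError(f"duplicate labels in {name}")

    @property
    def n_rows(self) -> int:
        return len(self.permeants) * len(self.vehicles) * max(1, len(self.membranes))

    def rows(self) -> pd.DataFrame:
        recs = []
        membranes = self.membranes or (None,)
        for p in self.permeants:
            for v in self.vehicles:
                for m in membranes:
                    rec = {"permeant": p, "vehicle": v}
                    if m is not None:
                        rec["membrane"] = m
                    recs.append(rec)
        return pd.DataFrame(recs)

    @classmethod
    def epidermis(cls, include_buffer: bool = False) -> "StudyDesign":
        """Permeant x vehicle subset (no membrane factor), 9 or 12 rows."""
        vehicles = ("IHD", "HD", "OA", "IPM")
        if include_buffer:
            vehicles = vehicles + ("Buffer",)
        return cls(vehicles=vehicles, membranes=())


@dataclass
class CorrelatedBlock:
    """Columns drawn jointly with equicorrelation ``r`` within the block."""

    names: tuple[str, ...]
    r: float

    def __post_init__(self) -> None:
        if not (0 <= abs(self.r) < 1):
            raise ValueError("block |r| must be in [0, 1)")
        if len(self.names) < 2:
            raise ValueError("a correlated block needs >= 2 columns")


@dataclass
class GeneratorConfig:
    """Planted-model configuration for :func:`generate_dataset`.

    ``planted_coefficients`` maps descriptor column names to their true
    standardized effects on the response; ``noise_sd`` is the response
    noise; correlated blocks add jointly drawn synthetic "supplied"
    descriptors; ``n_noise_descriptors`` adds pure-noise columns.
    """

    planted_coefficients: dict[str, float] = field(
        default_factory=lambda: {
            "solubility": 0.6,
            "lip_acc_vehicle": -0.5,
            "dH_membrane": -0.4,
        }
    )
    noise_sd: float = 0.1
    blocks: tuple[CorrelatedBlock, ...] = ()
    n_noise_descriptors: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        seen: set[str] = set()
        for b in self.blocks:
            dup = seen & set(b.names)
            if dup:
                raise ValueError(f"column(s) {sorted(dup)} appear in more than one block")
            seen |= set(b.names)


def _equicorrelated(rng: np.random.Generator, n: int, k: int, r: float) -> np.ndarray:
    cov = np.full((k, k), r)
    np.fill_diagonal(cov, 1.0)
    chol = np.linalg.cholesky(cov)
    return rng.standard_normal((n, k)) @ chol.T


# computed descriptors carried into the factorial table, per role
_VEHICLE_DESCRIPTORS = ("chi0", "chi1", "chi1_C", "lip_acc", "lip_don",
                        "opr_brigid", "KierFlex", "weight")
_PERMEANT_DESCRIPTORS = ("chi0", "chi0_C", "lip_acc", "lip_don", "weight")


def generate_dataset(
    design: StudyDesign | None = None,
    cfg: GeneratorConfig | None = None,
) -> tuple[pd.DataFrame, pd.Series, dict]:
    """Generate a factorial descriptor table with a planted response.

    Computed descriptors come from the fixture molecules (suffixed by
    role); supplied-type descriptors (solubility, melting point, log
    Ko/w, density, weight ratio, membrane HSP components, HSP distance)
    are drawn from plausible uniform ranges per factor level — they are
    synthetic stand-ins, not study measurements.  The response is

        y = sum_j beta_j * z_j + eps,   eps ~ N(0, noise_sd^2)

    with z_j the column-standardized planted descriptors.  Returns
    ``(table, y, truth)`` where truth records betas, noise, seed and
    column roles.
    """
    design = design or StudyDesign()
    cfg = cfg or GeneratorConfig()
    rng = np.random.default_rng(cfg.seed)
    table = design.rows()
    n = len(table)
    mols = fixture_molecules()
    hsp = default_hsp()

    roles: dict[str, str] = {}
    # computed descriptors per role
    for role, labels, wanted in (
        ("vehicle", design.vehicles, _VEHICLE_DESCRIPTORS),
        ("permeant", design.permeants, _PERMEANT_DESCRIPTORS),
    ):
        vecs = {}
        for lab in labels:
            if lab in mols:
                vecs[lab] = compute_descriptors(mols[lab]).as_dict()
        for d in wanted:
            col = f"{d}_{role}"
            if all(lab in vecs for lab in labels):
                table[col] = [vecs[lab][d] for lab in table[role]]
                roles[col] = role
    # membrane HSP components and the vehicle-membrane interaction distance
    if "membrane" in table.columns:
        for comp in ("dH", "dP"):
            col = f"{comp}_membrane"
            table[col] = [getattr(hsp[m], comp) for m in table["membrane"]]
            roles[col] = "membrane"
        table["hsp_distance"] = [
            hsp_distance(hsp[v], hsp[m])
            for v, m in zip(table["vehicle"], table["membrane"])
        ]
        roles["hsp_distance"] = "interaction"
        # solvent uptake proxy: per vehicle-membrane level
        wr = {
            (v, m): rng.uniform(1.0, 2.0)
            for v in design.vehicles for m in design.membranes
        }
        table["weight_ratio"] = [wr[(v, m)] for v, m in zip(table["vehicle"], table["membrane"])]
        roles["weight_ratio"] = "interaction"
    # supplied-type level descriptors
    sol = {
        (p, v): rng.uniform(1.0, 120.0)
        for p in design.permeants for v in design.vehicles
    }
    table["solubility"] = [sol[(p, v)] for p, v in zip(table["permeant"], table["vehicle"])]
    roles["solubility"] = "interaction"
    mpt = {p: rng.uniform(50.0, 250.0) for p in design.permeants}
    table["MPt_permeant"] = [mpt[p] for p in table["permeant"]]
    roles["MPt_permeant"] = "permeant"
    lko = {v: rng.uniform(3.0, 9.0) for v in design.vehicles}
    table["logKow_vehicle"] = [lko[v] for v in table["vehicle"]]
    roles["logKow_vehicle"] = "vehicle"
    dens = {v: rng.uniform(0.75, 0.95) for v in design.vehicles}
    table["density_vehicle"] = [dens[v] for v in table["vehicle"]]
    roles["density_vehicle"] = "vehicle"
    # correlated supplied blocks
    for block in cfg.blocks:
        draws = _equicorrelated(rng, n, len(block.names), block.r)
        for j, name in enumerate(block.names):
            table[name] = draws[:, j]
            roles[name] = "interaction"
    # pure-noise descriptors
    for j in range(cfg.n_noise_descriptors):
        col = f"noise_{j}"
        table[col] = rng.standard_normal(n)
        roles[col] = "interaction"

    missing = [c for c in cfg.planted_coefficients if c not in table.columns]
    if missing:
        raise ValueError(f"planted descriptors not in table: {missing}")
    y = np.zeros(n)
    for col, beta in cfg.planted_coefficients.items():
        x = table[col].to_numpy(dtype=float)
        y += beta * (x - x.mean()) / x.std(ddof=1)
    y += cfg.noise_sd * rng.standard_normal(n)
    truth = {
        "betas": dict(cfg.planted_coefficients),
        "noise_sd": cfg.noise_sd,
        "seed": cfg.seed,
        "roles": roles,
        "n_rows": n,
    }
    return table, pd.Series(y, name="response"), truth


# ---------------------------------------------------------------------------
# planted designs for recovery simulations
# ---------------------------------------------------------------------------

def planted_factor_matrix(
    n: int = 36,
    n_signal: int = 3,
    n_noise: int = 5,
    sigma: float = 0.1,
    seed: int = 0,
) -> tuple[pd.DataFrame, list[str], list[str]]:
    """One-factor design: ``n_signal`` columns follow a common latent
    factor (plus N(0, sigma) column noise); ``n_noise`` columns are pure
    noise.  Returns (matrix, signal names, noise names)."""
    rng = np.random.default_rng(seed)
    factor = rng.standard_normal(n)
    cols = {}
    signal = [f"sig_{i}" for i in range(n_signal)]
    noise = [f"noi_{i}" for i in range(n_noise)]
    for name in signal:
        cols[name] = factor + sigma * rng.standard_normal(n)
    for name in noise:
        cols[name] = rng.standard_normal(n)
    return pd.DataFrame(cols), signal, noise


def sparse_linear_dataset(
    n: int = 30,
    n_true: int = 3,
    n_decoy: int = 7,
    sigma: float = 0.1,
    seed: int = 0,
    betas: Optional[Sequence[float]] = None,
) -> tuple[pd.DataFrame, np.ndarray, dict]:
    """Independent-predictor design with a sparse linear response.

    The first ``n_true`` columns carry coefficients ``betas`` (default
    1.0, 0.8, 0.6, ...); decoys carry none.  Response noise is
    N(0, sigma).  Returns (X, y, truth)."""
    rng = np.random.default_rng(seed)
    p = n_true + n_decoy
    names = [f"true_{i}" for i in range(n_true)] + [f"decoy_{i}" for i in range(n_decoy)]
    X = pd.DataFrame(rng.standard_normal((n, p)), columns=names)
    if betas is None:
        betas = [1.0 - 0.2 * i for i in range(n_true)]
    betas = list(betas)
    if len(betas) != n_true or any(b == 0 for b in betas):
        raise ValueError("need one nonzero beta per true descriptor")
    z = (X - X.mean()) / X.std(ddof=1)
    y = z.iloc[:, :n_true].to_numpy() @ np.asarray(betas) + sigma * rng.standard_normal(n)
    truth = {"betas": dict(zip(names[:n_true], betas)), "sigma": sigma, "seed": seed}
    return X, y, truth


# ---------------------------------------------------------------------------
# Franz-cell forward simulator
# ---------------------------------------------------------------------------

DEFAULT_SCHEDULE = (0.5, 1.0, 1.5, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0)


def generate_franz_series(
    j_true: float,
    lag: float = 0.0,
    schedule: Sequence[float] = DEFAULT_SCHEDULE,
    noise_sd: float = 0.0,
    receptor_volume: float = 12.0,
    sample_volume: float = 0.2,
    area: float = 2.0,
    donor_concentration: Optional[float] = None,
    seed: int = 0,
) -> FranzCellSeries:
    """Forward-simulate receptor sampling under steady-state permeation.

    Mass enters the receptor at rate ``j_true * area`` (ug/h) once
    ``lag`` hours have elapsed.  At each scheduled timepoint the current
    receptor concentration is recorded (with N(0, noise_sd) measurement
    error, truncated at zero), then ``sample_volume`` mL is withdrawn
    and replaced with permeant-free medium.  Measurement noise perturbs
    the record only, not the mass balance, so the sampling correction is
    exactly invertible at ``noise_sd=0``.
    """
    if j_true < 0:
        raise ValueError("true flux must be >= 0")
    times = np.asarray(schedule, dtype=float)
    if np.any(np.diff(times) <= 0) or np.any(times < 0):
        raise ValueError("schedule must be strictly increasing and nonnegative")
    rng = np.random.default_rng(seed)
    mass = 0.0
    prev_t = 0.0
    measured = []
    for t in times:
        # mass entering between prev_t and t, honouring the lag
        mass += j_true * area * max(0.0, t - max(prev_t, lag))
        conc = mass / receptor_volume
        obs = conc + noise_sd * rng.standard_normal()
        measured.append(max(obs, 0.0))
        mass -= conc * sample_volume  # withdrawn aliquot; replaced clean
        prev_t = t
    return FranzCellSeries(
        times=times,
        concentrations=np.asarray(measured),
        receptor_volume=receptor_volume,
        sample_volume=sample_volume,
        area=area,
        donor_concentration=donor_concentration,
    )


def flux_stderr_known_sigma(
    series: FranzCellSeries,
    window: tuple[int, int],
    noise_sd: float,
) -> float:
    """Exact standard error of the windowed OLS slope under known,
    independent measurement noise on the concentrations.

    Each cumulative amount depends on the current concentration (weight
    V_r/A) and every earlier one (weight V_s/A); the slope is a linear
    functional of the Q values, so its variance propagates exactly.
    """
    lo, hi = window
    t = series.times[lo:hi]
    n_all = len(series.times)
    w = (t - t.mean()) / np.sum((t - t.mean()) ** 2)
    var = 0.0
    for i in range(n_all):
        acc = 0.0
        for k, nidx in enumerate(range(lo, hi)):
            if i == nidx:
                d = series.receptor_volume / series.area
            elif i < nidx:
                d = series.sample_volume / series.area
            else:
                d = 0.0
            acc += w[k] * d
        var += acc**2
    return noise_sd * np.sqrt(var)
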