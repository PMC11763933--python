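"""Synthetic EEG cohorts with known directed coupling and band content.

Each subject is a stable VAR(p) process over the channel graph of their
diagnostic class plus additive band-limited sinusoidal oscillations:
the VAR part gives exact ground truth for Granger-edge recovery, the
oscillations exercise frequency-band extraction. Class coupling graphs
are fixed data (acyclic, so any jittered coupling strength keeps the
process stable); per-subject jitter perturbs coupling strengths so each
class is a distribution rather than a point.

Defaults mirror a clinical resting EEG montage: 19 channels at 500 Hz,
150,000 samples per subject (five 60 s segments), five diagnostic
classes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import linalg

from .exceptions import ConfigurationError
from .io_preprocess import EEGRecording

CLASSES = ("alzheimer", "control", "depression", "mci", "schizophrenia")

#: Cohort sizes of the study population the generator emulates.
REFERENCE_CLASS_COUNTS = {
    "control": 95, "schizophrenia": 42, "depression": 28, "mci": 25, "alzheimer": 40,
}

#: Per-class oscillation spec: (centre frequency Hz, amplitude) pairs.
#: Frequencies sit in distinct clinical bands purely to make the bands
#: informative; they are synthetic choices, not physiological claims.
DEFAULT_OSCILLATIONS = {
    "control": [(10.0, 1.0)],        # alpha
    "schizophrenia": [(6.0, 1.0)],   # theta
    "mci": [(2.0, 1.0)],             # delta
    "depression": [(14.0, 1.0)],     # SMR
    "alzheimer": [(20.0, 1.0)],      # beta
}


def default_class_graphs() -> dict[str, np.ndarray]:
    """The five shipped class adjacency matrices (rows cause columns)."""
    raw = json.loads(
        resources.files("eeglgs.data").joinpath("class_graphs.json").read_text()
    )
    n = raw["n_channels"]
    graphs = {}
    for cls, edges in raw["graphs"].items():
        adj = np.zeros((n, n))
        for src, dst in edges:
            adj[src, dst] = 1.0
        graphs[cls] = adj
    return graphs


@dataclass
class SimulationConfig:
    """Cohort generation settings; defaults are the study conditions."""

    n_channels: int = 19
    fs: float = 500.0
    n_samples: int = 150_000
    var_order: int = 2
    self_coeffs: tuple[float, ...] = (0.5, -0.2)  # per-channel AR lags
    coupling: float = 0.5  # cross-channel lag-1 strength on graph edges
    jitter: float = 0.1  # +/- relative perturbation of coupling per subject
    innovation_sd: float = 1.0
    class_graphs: dict[str, np.ndarray] = field(default_factory=default_class_graphs)
    oscillations: dict[str, list[tuple[float, float]]] = field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_OSCILLATIONS.items()}
    )
    n_subjects_per_class: int = 20
    seed: int = 0
    burn_in: int = 500

    def __post_init__(self) -> None:
        if len(self.self_coeffs) != self.var_order:
            raise ConfigurationError(
                f"need {self.var_order} self coefficients, got {len(self.self_coeffs)}"
            )
        for cls, adj in self.class_graphs.items():
            adj = np.asarray(adj, dtype=np.float64)
            if adj.shape != (self.n_channels, self.n_channels):
                raise ConfigurationError(
                    f"class {cls!r} adjacency is {adj.shape}, "
                    f"expected {(self.n_channels, self.n_channels)}"
                )
            if np.any(np.diag(adj) != 0):
                raise ConfigurationError(f"class {cls!r} adjacency has nonzero diagonal")
            self.class_graphs[cls] = adj


@dataclass
class GroundTruth:
    """What was actually simulated for one subject."""

    subject_id: str
    class_label: str
    adjacency: np.ndarray  # template class graph (edge pattern)
    coupling_matrix: np.ndarray  # jittered lag-1 cross-coupling actually used
    seed: int


def _coefficient_matrices(
    cfg: SimulationConfig, coupling_matrix: np.ndarray
) -> list[np.ndarray]:
    """VAR coefficient matrices: self-lags on every diagonal, coupling at lag 1.

    Convention: A[j, i] multiplies channel i's lag when updating channel j,
    so an adjacency edge (i -> j) lands at A1[j, i].
    """
    mats = []
    for k, a in enumerate(cfg.self_coeffs):
        A = np.eye(cfg.n_channels) * a
        if k == 0:
            A += coupling_matrix.T
        mats.append(A)
    return mats


def companion_matrix(coeff_mats: list[np.ndarray]) -> np.ndarray:
    """Companion form of a VAR(p); stable iff spectral radius < 1."""
    p = len(coeff_mats)
    n = coeff_mats[0].shape[0]
    comp = np.zeros((n * p, n * p))
    comp[:n, :] = np.hstack(coeff_mats)
    if p > 1:
        comp[n:, : n * (p - 1)] = np.eye(n * (p - 1))
    return comp


def spectral_radius(coeff_mats: list[np.ndarray]) -> float:
    return float(np.max(np.abs(np.linalg.eigvals(companion_matrix(coeff_mats)))))


def stationary_covariance(coeff_mats: list[np.ndarray], innovation_sd: float) -> np.ndarray:
    """Analytic stationary covariance of the VAR component (companion Lyapunov)."""
    comp = companion_matrix(coeff_mats)
    n = coeff_mats[0].shape[0]
    Q = np.zeros_like(comp)
    Q[:n, :n] = np.eye(n) * innovation_sd**2
    S = linalg.solve_discrete_lyapunov(comp, Q)
    return S[:n, :n]


def _simulate_var(
    coeff_mats: list[np.ndarray], n_samples: int, innovation_sd: float,
    rng: np.random.Generator, burn_in: int,
) -> np.ndarray:
    p = len(coeff_mats)
    n_ch = coeff_mats[0].shape[0]
    total = n_samples + burn_in + p
    eps = rng.standard_normal((total, n_ch)) * innovation_sd
    y = np.zeros((total, n_ch))
    for t in range(p, total):
        acc = eps[t]
        for k, A in enumerate(coeff_mats, start=1):
            acc = acc + A @ y[t - k]
        y[t] = acc
    return y[p + burn_in :].T  # channels x samples


def simulate_subject(
    cfg: SimulationConfig, class_label: str, seed: int, subject_id: str | None = None
) -> tuple[EEGRecording, GroundTruth]:
    """Generate one subject: jittered class VAR plus class oscillations."""
    if class_label not in cfg.class_graphs:
        raise ConfigurationError(f"no coupling graph for class {class_label!r}")
    rng = np.random.default_rng(seed)
    adj = cfg.class_graphs[class_label]
    jitter = 1.0 + cfg.jitter * rng.uniform(-1.0, 1.0, size=adj.shape)
    coupling_matrix = adj * cfg.coupling * jitter
    coeff_mats = _coefficient_matrices(cfg, coupling_matrix)
    radius = spectral_radius(coeff_mats)
    if radius >= 1.0:
        raise ConfigurationError(
            f"class {class_label!r} VAR is unstable (spectral radius {radius:.4f})"
        )
    data = _simulate_var(coeff_mats, cfg.n_samples, cfg.innovation_sd, rng, cfg.burn_in)
    t = np.arange(cfg.n_samples) / cfg.fs
    for freq, amp in cfg.oscillations.get(class_label, []):
        phases = rng.uniform(0, 2 * np.pi, size=cfg.n_channels)
        data = data + amp * np.sin(2 * np.pi * freq * t[None, :] + phases[:, None])
    sid = subject_id or f"{class_label}_{seed}"
    rec = EEGRecording(
        data=data, fs=cfg.fs, subject_id=sid, class_label=class_label
    )
    truth = GroundTruth(
        subject_id=sid, class_label=class_label, adjacency=adj.copy(),
        coupling_matrix=coupling_matrix, seed=seed,
    )
    return rec, truth


def make_cohort(
    cfg: SimulationConfig, reference_proportions: bool = False
) -> tuple[list[EEGRecording], list[GroundTruth], pd.DataFrame]:
    """Generate a full multi-class cohort with a manifest.

    Per-subject seeds are derived deterministically from the master seed;
    ``reference_proportions`` uses the emulated study's class sizes
    (95/42/28/25/40) instead of ``n_subjects_per_class``.
    """
    counts = (
        dict(REFERENCE_CLASS_COUNTS)
        if reference_proportions
        else {cls: cfg.n_subjects_per_class for cls in sorted(cfg.class_graphs)}
    )
    total = sum(counts.values())
    child_seeds = [
        int(s) & 0x7FFFFFFF
        for s in np.random.SeedSequence(cfg.seed).generate_state(total)
    ]
    recordings, truths, rows = [], [], []
    idx = 0
    for cls in sorted(counts):
        for k in range(counts[cls]):
            sid = f"{cls}_{k:03d}"
            rec, truth = simulate_subject(cfg, cls, child_seeds[idx], subject_id=sid)
            recordings.append(rec)
            truths.append(truth)
            rows.append({"subject_id": sid, "class": cls, "seed": child_seeds[idx]})
            idx += 1
    manifest = pd.DataFrame(rows, columns=["subject_id", "class", "seed"])
    return recordings, truths, manifest


def write_cohort(
    recordings: list[EEGRecording],
    manifest: pd.DataFrame,
    outdir: str | Path,
    fmt: str = "csv",
) -> list[Path]:
    """Write recordings (CSV rows=channels, or EDF) plus manifest.csv."""
    from .io_preprocess import write_edf

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for rec in recordings:
        if fmt == "csv":
            p = outdir / f"{rec.subject_id}.csv"
            np.savetxt(p, rec.data, fmt="%.6g", delimiter=",")
        elif fmt == "edf":
            p = outdir / f"{rec.subject_id}.edf"
            write_edf(rec, p)
        else:
            raise ConfigurationError(f"unknown cohort format {fmt!r}")
        paths.append(p)
    mpath = outdir / "manifest.csv"
    manifest.to_csv(mpath, index=False)
    paths.append(mpath)
    return paths
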