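"""Synthetic expression compendia from the structural model Y = BY + Phi + E.

The generator draws a sparse, stable gene-gene interaction matrix B (zero
diagonal, spectral radius < 1), then produces sample columns by solving

    y = baseline + (I - B)^{-1} (phi + e),        e ~ N(0, noise_sd^2 I)

so that unperturbed training data (phi = 0) carry only network-propagated
noise, while test experiments add a known shift phi on their target genes.
Per-gene baselines mimic chip-style log2 intensities; they are not part of
the structural model and are centered out again during training.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import ExpressionCompendium

__all__ = [
    "TrueNetwork",
    "PerturbationSpec",
    "SimulationConfig",
    "generate_interaction_matrix",
    "simulate_samples",
    "generate_scenario",
    "write_ground_truth",
]


@dataclass(frozen=True)
class TrueNetwork:
    """Ground-truth interaction structure used to simulate data.

    ``B_true`` has an exactly zero diagonal and spectral radius < 1 so that
    the structural solve (I - B)^{-1} exists; ``baseline`` holds per-gene
    log-scale baseline expression levels.
    """

    genes: tuple[str, ...]
    B_true: np.ndarray
    baseline: np.ndarray

    def __post_init__(self) -> None:
        p = len(self.genes)
        if self.B_true.shape != (p, p):
            raise ValueError("B_true shape does not match gene list")
        if np.any(np.diag(self.B_true) != 0.0):
            raise ValueError("B_true diagonal must be exactly zero")
        if self.spectral_radius() >= 1.0:
            raise ValueError(
                "B_true spectral radius must be < 1 so that I - B is invertible"
            )

    def spectral_radius(self) -> float:
        if not np.any(self.B_true):
            return 0.0
        return float(np.max(np.abs(np.linalg.eigvals(self.B_true))))

    @property
    def p(self) -> int:
        return len(self.genes)


@dataclass(frozen=True)
class PerturbationSpec:
    """Additive shifts applied to target genes in a test experiment."""

    targets: tuple[str, ...]
    shifts: tuple[float, ...]
    label: str = ""

    def __post_init__(self) -> None:
        if len(self.targets) != len(set(self.targets)):
            raise ValueError("perturbation targets must be distinct")
        if len(self.shifts) != len(self.targets):
            raise ValueError("one shift per target required")
        if not all(math.isfinite(s) for s in self.shifts):
            raise ValueError("shifts must be finite")

    def as_vector(self, genes: tuple[str, ...] | list[str]) -> np.ndarray:
        index = {g: i for i, g in enumerate(genes)}
        unknown = [t for t in self.targets if t not in index]
        if unknown:
            raise ValueError(f"perturbation targets not in gene list: {unknown}")
        phi = np.zeros(len(genes))
        for t, s in zip(self.targets, self.shifts):
            phi[index[t]] = s
        return phi


EMPTY_PERTURBATION = PerturbationSpec(targets=(), shifts=(), label="none")


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for a simulated compendium.

    Defaults describe a small, sparse, moderately coupled network: 10% of
    off-diagonal entries nonzero with magnitudes 0.25-0.75 before a global
    rescale to spectral radius 0.5, homoscedastic Gaussian noise with
    sd 0.25 (log-scale units), baselines uniform in [6, 10], duplicate
    test experiments, and single-target shifts of 5x the noise sd.
    """

    p: int = 20
    n_train: int = 500
    density: float = 0.10
    strength_range: tuple[float, float] = (0.25, 0.75)
    spectral_target: float = 0.5
    noise_sd: float = 0.25
    replicates: int = 2
    seed: int = 0
    n_tests: int = 1
    targets_per_test: int = 1
    shift: float | None = None  # None -> 5 * noise_sd
    baseline_range: tuple[float, float] = (6.0, 10.0)

    def __post_init__(self) -> None:
        if self.p < 3:
            raise ValueError("p must be >= 3")
        if self.n_train < 2:
            raise ValueError("n_train must be >= 2")
        if not 0.0 <= self.density <= 1.0:
            raise ValueError("density must lie in [0, 1]")
        if not 0.0 < self.spectral_target < 1.0:
            raise ValueError("spectral_target must lie in (0, 1)")
        if self.noise_sd < 0.0:
            raise ValueError("noise_sd must be >= 0")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        for name in ("density", "spectral_target", "noise_sd"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        lo, hi = self.strength_range
        if not (math.isfinite(lo) and math.isfinite(hi)) or not 0 <= lo <= hi:
            raise ValueError("strength_range must be finite with 0 <= low <= high")
        if self.seed is None:
            raise ValueError("an explicit integer seed is required")

    @property
    def effective_shift(self) -> float:
        return 5.0 * self.noise_sd if self.shift is None else self.shift


def _gene_names(p: int) -> tuple[str, ...]:
    width = len(str(p))
    return tuple(f"G{str(i + 1).zfill(width)}" for i in range(p))


def generate_interaction_matrix(config: SimulationConfig) -> TrueNetwork:
    """Draw a sparse random interaction matrix rescaled to the target spectral radius.

    Off-diagonal support is chosen uniformly at random (``round(density *
    p*(p-1))`` entries), signs are symmetric Bernoulli, magnitudes uniform in
    ``strength_range``.  When the drawn matrix has a nonzero spectral radius
    it is globally rescaled so the radius equals ``spectral_target`` to a
    relative tolerance of 1e-6.  Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    p = config.p
    genes = _gene_names(p)
    B = np.zeros((p, p))
    off_diag = [(i, j) for i in range(p) for j in range(p) if i != j]
    n_edges = int(round(config.density * len(off_diag)))
    if n_edges > 0:
        chosen = rng.choice(len(off_diag), size=n_edges, replace=False)
        lo, hi = config.strength_range
        magnitudes = rng.uniform(lo, hi, size=n_edges)
        signs = rng.choice([-1.0, 1.0], size=n_edges)
        for idx, mag, sign in zip(chosen, magnitudes, signs):
            i, j = off_diag[idx]
            B[i, j] = sign * mag
        radius = float(np.max(np.abs(np.linalg.eigvals(B))))
        if radius > 0:
            B *= config.spectral_target / radius
        # A nilpotent draw (radius 0, e.g. triangular support) cannot be
        # rescaled; it is already stable and left as drawn.
    baseline = rng.uniform(*config.baseline_range, size=p)
    return TrueNetwork(genes=genes, B_true=B, baseline=baseline)


def simulate_samples(
    net: TrueNetwork,
    n: int,
    noise_sd: float,
    pert: PerturbationSpec = EMPTY_PERTURBATION,
    seed: int = 0,
    sample_prefix: str = "S",
) -> ExpressionCompendium:
    """Simulate ``n`` sample columns from the structural model.

    Each column is ``baseline + (I - B)^{-1} (phi + e)`` with i.i.d. Gaussian
    noise e.  ``pert`` contributes the shift vector phi (zero when empty).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    p = net.p
    phi = pert.as_vector(net.genes)
    A = np.eye(p) - net.B_true
    # Guarded by the TrueNetwork invariant, but solve defensively anyway.
    try:
        inv = np.linalg.inv(A)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "I - B is singular; the interaction matrix violates the "
            "spectral-radius-below-one invariant"
        ) from exc
    noise = rng.normal(0.0, noise_sd, size=(p, n)) if noise_sd > 0 else np.zeros((p, n))
    values = net.baseline[:, None] + inv @ (phi[:, None] + noise)
    samples = [f"{sample_prefix}{i + 1}" for i in range(n)]
    meta = {
        s: {"condition": pert.label or "unperturbed", "replicate": str(i + 1)}
        for i, s in enumerate(samples)
    }
    frame = pd.DataFrame(values, index=list(net.genes), columns=samples)
    return ExpressionCompendium(frame, metadata=meta)


def generate_scenario(
    config: SimulationConfig,
) -> tuple[TrueNetwork, ExpressionCompendium, list[tuple[PerturbationSpec, ExpressionCompendium]]]:
    """Build a full study: network, unperturbed training data, test experiments.

    The training compendium has phi = 0 throughout.  Each of ``n_tests``
    experiments perturbs ``targets_per_test`` distinct genes (disjoint
    across experiments while genes last) by ``effective_shift`` and carries
    ``replicates`` columns sharing one :class:`PerturbationSpec`.  Fully
    reproducible from ``config.seed``.
    """
    net = generate_interaction_matrix(config)
    train = simulate_samples(
        net,
        config.n_train,
        config.noise_sd,
        seed=config.seed + 1,
        sample_prefix="train",
    )
    rng = np.random.default_rng(config.seed + 2)
    order = rng.permutation(config.p)
    tests: list[tuple[PerturbationSpec, ExpressionCompendium]] = []
    cursor = 0
    for t in range(config.n_tests):
        if cursor + config.targets_per_test > config.p:
            cursor = 0
        targets = tuple(net.genes[g] for g in order[cursor : cursor + config.targets_per_test])
        cursor += config.targets_per_test
        spec = PerturbationSpec(
            targets=targets,
            shifts=tuple(config.effective_shift for _ in targets),
            label=f"pert{t + 1}",
        )
        experiment = simulate_samples(
            net,
            config.replicates,
            config.noise_sd,
            pert=spec,
            seed=config.seed + 1000 + t,
            sample_prefix=f"pert{t + 1}_rep",
        )
        tests.append((spec, experiment))
    return net, train, tests


def write_ground_truth(net: TrueNetwork, tests, out_dir) -> None:
    """Write simulation ground truth as plain-text tables.

    ``true_network.tsv`` is a 3-column sparse edge list (source, target,
    coefficient); ``true_targets.tsv`` flags each gene's target status and
    shift per experiment.
    """
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows_i, cols_j = np.nonzero(net.B_true)
    edges = pd.DataFrame(
        {
            "source": [net.genes[j] for j in cols_j],
            "target": [net.genes[i] for i in rows_i],
            "coefficient": net.B_true[rows_i, cols_j],
        }
    )
    edges.to_csv(out_dir / "true_network.tsv", sep="\t", index=False)
    records = []
    for spec, _ in tests:
        shifts = dict(zip(spec.targets, spec.shifts))
        for g in net.genes:
            records.append(
                {
                    "experiment": spec.label,
                    "gene": g,
                    "true_target": int(g in shifts),
                    "shift": shifts.get(g, 0.0),
                }
            )
    pd.DataFrame(records).to_csv(out_dir / "true_targets.tsv", sep="\t", index=False)
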