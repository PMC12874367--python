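"""State populations: residence fractions, angle densities, Boltzmann weights.

Residence-time analysis counts the fraction of trajectory frames spent
in each conformational state — equivalently the integral of the
theta_min density over each state's angle interval.  Independently,
Boltzmann populations weight an ensemble of energy-labelled structures
(e.g. the relaxed-scan grid) by exp(-E/kBT) and sum per state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import gaussian_kde

from .conformation import STATES, StateLabel, Thresholds
from .errors import ConfigError, DataError

__all__ = [
    "KB_KCAL",
    "BoltzmannSpec",
    "PopulationSummary",
    "AngleDensity",
    "residence_fractions",
    "angle_density",
    "integrate_density",
    "boltzmann_populations",
]

#: Boltzmann constant in kcal mol^-1 K^-1
KB_KCAL = 0.0019872041


@dataclass(frozen=True)
class BoltzmannSpec:
    """Temperature and constants for Boltzmann weighting."""

    temperature: float = 298.15  # K
    kb: float = KB_KCAL

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ConfigError(f"temperature must be > 0, got {self.temperature}")

    @property
    def kbt(self) -> float:
        return self.kb * self.temperature


@dataclass
class PopulationSummary:
    """Residence-time fractions, pooled over replicas."""

    fractions: dict[str, float]
    counts: dict[str, int]
    n_frames: int
    burn_in: int
    per_replica: list[dict[str, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        s = sum(self.fractions.values())
        if abs(s - 1.0) > 1e-12:
            raise ValueError(f"fractions sum to {s}, not 1")
        if any(v < 0 for v in self.fractions.values()):
            raise ValueError("fractions must be nonnegative")


def _count_states(series: Sequence[str]) -> dict[str, int]:
    counts = {s: 0 for s in STATES}
    for s in series:
        if s not in counts:
            raise DataError(f"unknown state label {s!r}")
        counts[s] += 1
    return counts


def residence_fractions(
    states: Sequence[str] | Sequence[Sequence[str]],
    burn_in: int = 0,
) -> PopulationSummary:
    """Fraction of frames per state, after discarding *burn_in* frames.

    *states* may be one label series or a list of replica series; the
    pooled estimate weights replicas by their (post-burn-in) frame
    counts, i.e. it is a plain count over all pooled frames.
    """
    if len(states) == 0:
        raise DataError("empty state series")
    replicas: list[Sequence[str]]
    if isinstance(states[0], str):
        replicas = [states]  # type: ignore[list-item]
    else:
        replicas = list(states)  # type: ignore[arg-type]
    total = {s: 0 for s in STATES}
    per_rep: list[dict[str, float]] = []
    n_total = 0
    for rep in replicas:
        if burn_in >= len(rep):
            raise DataError(
                f"burn-in {burn_in} >= series length {len(rep)}"
            )
        counts = _count_states(rep[burn_in:])
        n = sum(counts.values())
        per_rep.append({s: counts[s] / n for s in STATES})
        for s in STATES:
            total[s] += counts[s]
        n_total += n
    fractions = {s: total[s] / n_total for s in STATES}
    # remove floating error so the invariant (sum == 1) is exact
    return PopulationSummary(
        fractions=fractions,
        counts=total,
        n_frames=n_total,
        burn_in=burn_in,
        per_replica=per_rep,
    )


@dataclass
class AngleDensity:
    """Normalized density of theta_min over [0, 90] deg on bin supports."""

    edges: np.ndarray  # (B+1,) increasing, within [0, 90]
    density: np.ndarray  # (B,) per-degree density, integral == 1
    estimator: str = "histogram"

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    def integral(self) -> float:
        return float(np.sum(self.density * np.diff(self.edges)))


def _aligned_edges(bins: int, thresholds: Thresholds | None) -> np.ndarray:
    edges = np.linspace(0.0, 90.0, bins + 1)
    if thresholds is not None:
        edges = np.unique(
            np.concatenate(
                [edges, [thresholds.open_max, thresholds.semiopen_max]]
            )
        )
    return edges


def angle_density(
    theta_min: Sequence[float],
    bins: int = 90,
    estimator: str = "histogram",
    bandwidth: float | str | None = None,
    thresholds: Thresholds | None = Thresholds(),
) -> AngleDensity:
    """Density estimate of the theta_min series on [0, 90] degrees.

    ``histogram`` (default) uses *bins* equal-width bins with the state
    thresholds inserted as extra edges, so that integrating over a state
    interval reproduces frame counting exactly.  ``kde`` evaluates a
    Gaussian kernel estimate on a fine grid (901 points) and
    renormalizes over [0, 90].
    """
    x = np.asarray(theta_min, dtype=float)
    if x.size == 0:
        raise DataError("empty angle series")
    if ((x < 0) | (x > 90)).any():
        raise DataError("theta values must lie in [0, 90] degrees")
    if estimator == "histogram":
        edges = _aligned_edges(bins, thresholds)
        counts, _ = np.histogram(x, bins=edges)
        widths = np.diff(edges)
        dens = counts / counts.sum() / widths
        return AngleDensity(edges=edges, density=dens, estimator="histogram")
    if estimator == "kde":
        if x.std() == 0:
            # degenerate sample: fall back to a one-bin histogram spike
            return angle_density(x, bins=bins, estimator="histogram",
                                 thresholds=thresholds)
        kde = gaussian_kde(x, bw_method=bandwidth)
        edges = np.linspace(0.0, 90.0, 901)
        centers = 0.5 * (edges[:-1] + edges[1:])
        dens = kde(centers)
        dens /= np.sum(dens * np.diff(edges))
        return AngleDensity(edges=edges, density=dens, estimator="kde")
    raise ConfigError(f"unknown density estimator {estimator!r}")


def integrate_density(
    density: AngleDensity, thresholds: Thresholds = Thresholds()
) -> dict[str, float]:
    """Integrate the density over each state's theta interval.

    open: [0, open_max]; semiopen: (open_max, semiopen_max];
    closed: (semiopen_max, 90].  Bins straddling a threshold contribute
    proportionally to their overlap; with threshold-aligned bins (the
    histogram default) the result equals direct frame counting.
    """
    t = thresholds
    if not (0 < t.open_max < t.semiopen_max < 90):
        raise ConfigError("thresholds outside (0, 90)")
    if abs(density.integral() - 1.0) > 1e-9:
        raise DataError("density is not normalized")
    bounds = {
        "open": (0.0, t.open_max),
        "semiopen": (t.open_max, t.semiopen_max),
        "closed": (t.semiopen_max, 90.0),
    }
    lo_e = density.edges[:-1]
    hi_e = density.edges[1:]
    out: dict[str, float] = {}
    for state, (lo, hi) in bounds.items():
        overlap = np.clip(
            np.minimum(hi_e, hi) - np.maximum(lo_e, lo), 0.0, None
        )
        out[state] = float(np.sum(density.density * overlap))
    total = sum(out.values())
    out = {s: v / total for s, v in out.items()}
    return out


def boltzmann_populations(
    energies: Sequence[float],
    labels: Sequence[str],
    spec: BoltzmannSpec = BoltzmannSpec(),
) -> dict[str, float]:
    """Boltzmann-weighted state populations of an energy-labelled ensemble.

    w_i = exp(-(E_i - E_min) / kBT); population(state) = sum of w over
    that state's structures / sum over all.  Centering at E_min makes
    the exponentials underflow-safe and leaves populations unchanged
    (shift invariance).
    """
    e = np.asarray(energies, dtype=float)
    if e.size == 0:
        raise DataError("empty energy list")
    if not np.isfinite(e).all():
        raise DataError("energies must be finite")
    if len(labels) != e.size:
        raise DataError("label and energy counts differ")
    w = np.exp(-(e - e.min()) / spec.kbt)
    z = w.sum()
    out = {s: 0.0 for s in STATES}
    for wi, lab in zip(w, labels):
        if lab not in out:
            raise DataError(f"unknown state label {lab!r}")
        out[lab] += float(wi)
    return {s: v / z for s, v in out.items()}
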