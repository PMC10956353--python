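"""Species-abundance models and depth assignment.

Abundances are drawn empirically from an environment pool (all relative
abundances observed across that environment's samples) or, for user-supplied
profiles, from a log-normal fitted to them.  Both samplers use the same
rejection-then-normalize contract: raw draws are repeated until their sum is
within ``epsilon`` of 1, then divided by the sum, so normalization perturbs
the drawn values as little as possible.  Relative abundances are finally
converted to per-genome sequencing depths by linear scaling anchored at
either the minimum or the mean depth.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np


@dataclass
class AbundancePool:
    """All species relative abundances pooled over one environment's samples."""

    environment: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size and (np.any(self.values <= 0) or np.any(self.values > 1)):
            raise ValueError("pool values must lie in (0, 1]")


@dataclass
class LogNormalFit:
    """Maximum-likelihood log-normal parameters of an abundance distribution."""

    mu: float
    sigma_ln: float

    def __post_init__(self) -> None:
        if self.sigma_ln < 0:
            raise ValueError("sigma_ln must be >= 0")


@dataclass
class DepthSpec:
    """Target sequencing depth: either the minimum or the mean fold coverage."""

    kind: str  # "min" | "mean"
    value: float

    def __post_init__(self) -> None:
        if self.kind not in ("min", "mean"):
            raise ValueError(f"kind must be 'min' or 'mean', got {self.kind!r}")
        if not self.value > 0:
            raise ValueError("depth value must be > 0")


@dataclass
class AbundanceDraw:
    """A normalized abundance draw plus rejection-loop diagnostics."""

    values: np.ndarray  # normalized, sums to 1
    raw_sum: float
    tries: int
    accepted: bool


@dataclass
class AbundanceProfile:
    """Final species -> relative abundance map, summing to one."""

    abundances: dict[str, float]

    def __post_init__(self) -> None:
        if not self.abundances:
            raise ValueError("profile must be non-empty")
        for sp, a in self.abundances.items():
            if not a > 0:
                raise ValueError(f"abundance for {sp!r} must be > 0")
        total = sum(self.abundances.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"abundances must sum to 1 (got {total!r})")

    @property
    def species(self) -> list[str]:
        return list(self.abundances)

    def write_tsv(self, path, depths: dict[str, float] | None = None) -> None:
        with open(path, "w") as fh:
            header = "species\tabundance" + ("\tdepth" if depths is not None else "")
            fh.write("#" + header + "\n")
            for sp, a in self.abundances.items():
                row = f"{sp}\t{a!r}"
                if depths is not None:
                    row += f"\t{depths[sp]!r}"
                fh.write(row + "\n")


def make_profile(species, values) -> AbundanceProfile:
    values = np.asarray(values, dtype=float)
    if len(species) != values.size:
        raise ValueError("species and values differ in length")
    return AbundanceProfile(dict(zip(species, values.tolist())))


def _rejection_sample(draw_raw, n, epsilon, max_tries, what):
    if n < 1:
        raise ValueError("need at least one species")
    if not 0 < epsilon < 1:
        raise ValueError("epsilon must lie in (0, 1)")
    best = None
    for t in range(1, max_tries + 1):
        raw = draw_raw(n)
        s = float(raw.sum())
        dev = abs(s - 1.0)
        if best is None or dev < best[0]:
            best = (dev, raw, s)
        if dev <= epsilon:
            return AbundanceDraw(values=raw / s, raw_sum=s, tries=t, accepted=True)
    warnings.warn(
        f"{what}: no draw of {n} values reached |sum-1| <= {epsilon} in "
        f"{max_tries} tries; normalizing the closest (|sum-1|={best[0]:.3g})",
        stacklevel=3,
    )
    _, raw, s = best
    return AbundanceDraw(values=raw / s, raw_sum=s, tries=max_tries, accepted=False)


def sample_abundances(
    pool, n: int, epsilon: float = 0.25, max_tries: int = 1000, rng=None
) -> AbundanceDraw:
    """Draw ``n`` abundances with replacement from an environment pool.

    Raw draws are rejected until their sum approximates 1 (within
    ``epsilon``), then normalized to sum exactly 1; after ``max_tries`` the
    closest-sum draw is normalized with a warning.
    """
    values = pool.values if isinstance(pool, AbundancePool) else np.asarray(pool, dtype=float)
    if values.size == 0:
        raise ValueError("abundance pool is empty")
    rng = np.random.default_rng(rng)
    return _rejection_sample(
        lambda k: rng.choice(values, size=k, replace=True),
        n,
        epsilon,
        max_tries,
        "empirical abundance sampling",
    )


def fit_lognormal(values) -> LogNormalFit:
    """Fit a log-normal by maximum likelihood (moments of the log values)."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 values to fit")
    if np.any(values <= 0):
        raise ValueError("all values must be > 0 to fit a log-normal")
    logs = np.log(values)
    return LogNormalFit(mu=float(np.mean(logs)), sigma_ln=float(np.std(logs)))


def sample_lognormal(
    fit: LogNormalFit, n: int, epsilon: float = 0.25, max_tries: int = 1000, rng=None
) -> AbundanceDraw:
    """Draw ``n`` abundances from a fitted log-normal (same contract as
    :func:`sample_abundances`)."""
    rng = np.random.default_rng(rng)
    return _rejection_sample(
        lambda k: np.exp(rng.normal(fit.mu, fit.sigma_ln, size=k)),
        n,
        epsilon,
        max_tries,
        "log-normal abundance sampling",
    )


def assign_depths(profile: AbundanceProfile, spec: DepthSpec) -> dict[str, float]:
    """Convert relative abundances to fold-coverage depths, linearly.

    ``min`` anchors the least-abundant species at the target depth; ``mean``
    anchors the average depth.  Depth order always follows abundance order.
    """
    a = np.array(list(profile.abundances.values()), dtype=float)
    anchor = a.min() if spec.kind == "min" else a.mean()
    depths = spec.value * (a / anchor)  # anchor element scales by exactly 1.0
    return dict(zip(profile.abundances, depths.tolist()))
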