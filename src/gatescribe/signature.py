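"""Per-marker expression-level calling.

Each marker's intensity distribution is modeled as a univariate Gaussian
mixture

    p(x) = sum_i  phi_i N(x | mu_i, sigma_i),   i = 1..G,  G in {2, 3},

fitted by expectation-maximization, and every cell is assigned to the
maximum-a-posteriori component.  Components are ordered by their means, so
the lowest-mean component is read as negative (-), the highest as positive
(+), and the middle one — present only when G = 3 — as medium (m).

Two variance parameterizations are supported: E (equal — all components
share one standard deviation) and V (variable — each component owns its
own).  Cytometry marker distributions are often strongly skewed, which
drags mixture components toward the heavy tail; as an optional
preconditioner, ranked set sampling (RSS) with set size m = 2 builds a
fitting sample biased toward the tail opposite the skew (leftmost stratum
for left/symmetric distributions, rightmost for right-skewed ones),
sharpening the bimodality the EM has to resolve.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from scipy.special import logsumexp

from .errors import DegenerateDataError, ParameterError
from .io import ExpressionMatrix

LEVEL_SYMBOLS = {2: ("-", "+"), 3: ("-", "m", "+")}

_EM_MAX_ITER = 500
_EM_REL_TOL = 1e-8
_SD_FLOOR_FRACTION = 1e-6


@dataclass
class GMMFit:
    """A fitted univariate Gaussian mixture, components sorted by mean."""

    means: np.ndarray
    sds: np.ndarray
    weights: np.ndarray
    G: int
    variance_mode: str
    converged: bool = True
    log_likelihood: float = float("nan")

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=float)
        self.sds = np.asarray(self.sds, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if not (len(self.means) == len(self.sds) == len(self.weights) == self.G):
            raise ParameterError("component arrays must all have length G")
        if abs(self.weights.sum() - 1.0) > 1e-9:
            raise ParameterError("mixture weights must sum to 1")
        if np.any(np.diff(self.means) <= 0):
            raise ParameterError("component means must be strictly ascending")
        if np.any(self.sds <= 0):
            raise ParameterError("component standard deviations must be positive")


@dataclass
class RSSConfig:
    """Ranked-set-sampling configuration; the set size is fixed at 2."""

    n_cycles: int = 50_000
    seed: int = 0
    m: int = field(default=2, init=False)

    def __post_init__(self) -> None:
        if self.n_cycles < 1:
            raise ParameterError("n_cycles must be >= 1")


@dataclass
class SignatureMatrix:
    """Categorical expression level (-, m, +) per cell per modeled marker."""

    levels: np.ndarray  # dtype '<U1', cells x markers
    marker_names: list[str]

    @property
    def n_cells(self) -> int:
        return self.levels.shape[0]

    def column(self, marker: str) -> np.ndarray:
        return self.levels[:, self.marker_names.index(marker)]

    def row_mapping(self, i: int) -> dict[str, str]:
        return dict(zip(self.marker_names, self.levels[i]))

    def encoded(self) -> np.ndarray:
        """Ordinal encoding - < m < + as 0 < 1 < 2."""
        out = np.zeros(self.levels.shape, dtype=np.int8)
        out[self.levels == "m"] = 1
        out[self.levels == "+"] = 2
        return out


def compute_skewness(values: Sequence[float]) -> float:
    """Biased sample skewness g1 = m3 / m2^(3/2); 0 for constant input."""
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ParameterError("skewness needs at least 3 observations")
    if np.ptp(x) == 0 or np.var(x) == 0:
        return 0.0
    return float(stats.skew(x, bias=True))


def ranked_set_sample(
    values: Sequence[float], config: RSSConfig
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Draw the leftmost and rightmost RSS strata with set size 2.

    Per cycle, four points are drawn with replacement and arranged into two
    ranked sets of two; the minimum of the first set feeds the leftmost
    stratum and the maximum of the second the rightmost.  Returns
    (leftmost, rightmost, ok); with fewer than 4 values the input is
    returned for both strata and ok is False.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 4:
        warnings.warn("fewer than 4 values: RSS falls back to the full sample")
        return x.copy(), x.copy(), False
    rng = np.random.default_rng(config.seed)
    draws = rng.choice(x, size=(config.n_cycles, 2, 2), replace=True)
    leftmost = draws[:, 0, :].min(axis=1)
    rightmost = draws[:, 1, :].max(axis=1)
    return leftmost, rightmost, True


def select_tail_sample(values: Sequence[float], config: RSSConfig) -> np.ndarray:
    """RSS stratum opposite the skew: rightmost for positive skewness,
    leftmost otherwise (symmetric distributions select leftmost)."""
    leftmost, rightmost, _ = ranked_set_sample(values, config)
    return rightmost if compute_skewness(values) > 0 else leftmost


def _em_once(x: np.ndarray, G: int, variance_mode: str) -> GMMFit:
    n = x.size
    # quantile-based init: component means at the (i - 0.5)/G quantiles
    means = np.quantile(x, (np.arange(G) + 0.5) / G)
    pooled_sd = x.std()
    sds = np.full(G, pooled_sd)
    weights = np.full(G, 1.0 / G)
    sd_floor = max(_SD_FLOOR_FRACTION * pooled_sd, 1e-12)

    prev_ll = -np.inf
    converged = False
    for _ in range(_EM_MAX_ITER):
        # E-step in log space
        log_comp = (
            np.log(weights)[:, None]
            + stats.norm.logpdf(x[None, :], means[:, None], sds[:, None])
        )
        log_norm = logsumexp(log_comp, axis=0)
        ll = float(log_norm.sum())
        resp = np.exp(log_comp - log_norm[None, :])

        # M-step
        nk = resp.sum(axis=1)
        nk = np.maximum(nk, 1e-300)
        weights = nk / n
        means = (resp @ x) / nk
        sq = resp * (x[None, :] - means[:, None]) ** 2
        if variance_mode == "E":
            shared = np.sqrt(sq.sum() / n)
            sds = np.full(G, max(shared, sd_floor))
        else:
            sds = np.sqrt(sq.sum(axis=1) / nk)
            sds = np.maximum(sds, sd_floor)

        if np.isfinite(prev_ll) and abs(ll - prev_ll) <= _EM_REL_TOL * abs(prev_ll):
            converged = True
            prev_ll = ll
            break
        prev_ll = ll

    order = np.argsort(means, kind="stable")
    means, sds, weights = means[order], sds[order], weights[order]
    # collapse numerically tied means so the strict-ordering invariant holds
    for i in range(1, G):
        if means[i] <= means[i - 1]:
            means[i] = means[i - 1] + max(1e-9, 1e-9 * abs(means[i - 1]))
    weights = weights / weights.sum()
    return GMMFit(
        means=means,
        sds=sds,
        weights=weights,
        G=G,
        variance_mode=variance_mode,
        converged=converged,
        log_likelihood=prev_ll,
    )


def fit_marker_gmm(
    values: Sequence[float], G: int = 2, variance_mode: str = "E", seed: int = 0
) -> GMMFit:
    """EM fit of a G-component univariate mixture (G in {2, 3}).

    Initialization is deterministic (quantile means, uniform weights,
    pooled-variance sds), so the fit is reproducible irrespective of seed;
    the seed parameter is accepted for interface uniformity with the
    sampling steps.
    """
    if G not in (2, 3):
        raise ParameterError(f"G must be 2 or 3, got {G}")
    if variance_mode not in ("E", "V"):
        raise ParameterError(f"variance_mode must be 'E' or 'V', got {variance_mode!r}")
    x = np.asarray(values, dtype=float)
    if np.ptp(x) == 0:
        raise DegenerateDataError("all values identical: cannot fit a mixture")
    if x.size < 10 * G:
        raise ParameterError(f"need at least {10 * G} values to fit G={G}")
    fit = _em_once(x, G, variance_mode)
    if not fit.converged:
        warnings.warn("EM did not converge within the iteration cap; best iterate returned")
    return fit


def assign_expression_levels(values: Sequence[float], fit: GMMFit) -> np.ndarray:
    """Maximum-a-posteriori component per value, reported as level symbols.

    The component maximizing phi_i N(x | mu_i, sigma_i) wins; exact ties go
    to the lower-mean component.
    """
    x = np.asarray(values, dtype=float)
    log_post = (
        np.log(fit.weights)[:, None]
        + stats.norm.logpdf(x[None, :], fit.means[:, None], fit.sds[:, None])
    )
    # argmax returns the first (lowest-mean) index on ties
    comp = np.argmax(log_post, axis=0)
    symbols = np.array(LEVEL_SYMBOLS[fit.G])
    return symbols[comp]


def build_signature_matrix(
    matrix: ExpressionMatrix,
    levels_per_marker: Mapping[str, int],
    variance_mode: str = "E",
    use_rss: bool = False,
    seed: int = 0,
    rss_cycles: int | None = None,
) -> tuple[SignatureMatrix, dict[str, GMMFit]]:
    """Call the expression level of every cell for each requested marker.

    Each marker is fitted independently: optionally the fitting sample is
    replaced by the skew-opposing RSS stratum, then a G-component mixture
    (G from ``levels_per_marker``) is fitted and applied to all cells.
    Markers absent from ``levels_per_marker`` are skipped.  Per-marker
    fitting failures are collected and re-raised with marker names.
    """
    missing = [m for m in levels_per_marker if m not in matrix.marker_names]
    if missing:
        raise ParameterError(f"markers not in the expression matrix: {missing}")
    markers = [m for m in matrix.marker_names if m in levels_per_marker]
    n = matrix.n_cells
    columns = []
    fits: dict[str, GMMFit] = {}
    failures: list[str] = []
    for j, marker in enumerate(markers):
        x = matrix.column(marker)
        sample = x
        if use_rss:
            cycles = rss_cycles if rss_cycles is not None else min(n, 50_000)
            cfg = RSSConfig(n_cycles=cycles, seed=(seed + j) % (2**31))
            sample = select_tail_sample(x, cfg)
        try:
            fit = fit_marker_gmm(sample, G=levels_per_marker[marker], variance_mode=variance_mode, seed=seed)
        except DegenerateDataError as exc:
            failures.append(f"{marker}: {exc}")
            continue
        fits[marker] = fit
        columns.append(assign_expression_levels(x, fit))
    if failures:
        raise DegenerateDataError("; ".join(failures))
    levels = np.stack(columns, axis=1) if columns else np.empty((n, 0), dtype="<U1")
    return SignatureMatrix(levels=levels, marker_names=markers), fits


def gmm_summary_frame(fits: Mapping[str, GMMFit]):
    """Per-marker component parameters as a tidy table (diagnostics)."""
    import pandas as pd

    rows = []
    for marker, fit in fits.items():
        for i in range(fit.G):
            rows.append(
                {
                    "marker": marker,
                    "component": i,
                    "mean": fit.means[i],
                    "sd": fit.sds[i],
                    "weight": fit.weights[i],
                    "variance_mode": fit.variance_mode,
                }
            )
    return pd.DataFrame(rows)
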