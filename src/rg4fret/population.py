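"""Population FRET histograms and multi-peak Gaussian decomposition.

Pooled per-molecule FRET samples (30-50 frames per molecule) are binned
into a population histogram and decomposed into K Gaussian components whose
areas, normalized to the total mass, give the occupancy of each folding
state: the lowest-center component is the unfolded ssRNA pool, the highest
the well-folded G4 pool, and intermediates (G-hairpin, G-triplex) lie in
between.  Titration curves across KCl concentrations and before/after
comparisons (helicase unwinding) are assembled from these fractions with
molecule-level bootstrap confidence intervals.

The decomposition is fit by maximum-likelihood EM on the raw samples, with
component widths bounded (default [0.01, 0.15] FRET units) so no single
broad component can swallow the histogram, and with optional anchoring of
the centers near HMM-derived state means to stabilize fits of sparsely
occupied states.  A binned weighted-least-squares fit is available as an
alternative for parity with curve-fitting workflows.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize, stats
from scipy.special import logsumexp

__all__ = [
    "FretHistogram",
    "HistogramDecomposition",
    "ConditionFit",
    "TitrationResult",
    "ComparisonResult",
    "build_histogram",
    "fit_gaussian_mixture",
    "state_fractions",
    "default_state_labels",
    "fit_condition",
    "titration_curve",
    "compare_conditions",
]

DEFAULT_WIDTH_BOUNDS = (0.01, 0.15)


def default_state_labels(n_states: int) -> tuple[str, ...]:
    """Folding-pathway labels in ascending FRET order."""
    if n_states == 4:
        return ("ssRNA", "G-hairpin", "G-triplex", "G4")
    if n_states == 3:
        return ("ssRNA", "G-hairpin", "G-triplex")
    if n_states == 2:
        return ("unfolded", "folded")
    if n_states == 1:
        return ("state_0",)
    return tuple(f"state_{i}" for i in range(n_states))


@dataclass(frozen=True)
class FretHistogram:
    """Fixed-width population histogram on the FRET axis."""

    bin_edges: np.ndarray
    counts: np.ndarray
    n_molecules: int
    n_samples: int

    def __post_init__(self):
        edges = np.asarray(self.bin_edges, dtype=float)
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.size != edges.size - 1:
            raise ValueError("counts must have one fewer entry than bin_edges")
        if np.any(np.diff(edges) <= 0):
            raise ValueError("bin_edges must be strictly ascending")
        if np.any(counts < 0) or counts.sum() != self.n_samples:
            raise ValueError("counts must be non-negative and sum to n_samples")
        object.__setattr__(self, "bin_edges", edges)
        object.__setattr__(self, "counts", counts)

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


def build_histogram(
    samples,
    bin_width: float = 0.02,
    value_range: tuple[float, float] = (0.0, 1.0),
    n_molecules: int | None = None,
) -> FretHistogram:
    """Bin pooled FRET samples into half-open bins (last bin closed)."""
    x = np.asarray(samples, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("cannot build a histogram from an empty sample set")
    lo, hi = value_range
    n_bins = int(round((hi - lo) / bin_width))
    edges = np.linspace(lo, hi, n_bins + 1)
    counts, _ = np.histogram(np.clip(x, lo, hi), bins=edges)
    return FretHistogram(
        bin_edges=edges,
        counts=counts,
        n_molecules=n_molecules if n_molecules is not None else x.size,
        n_samples=x.size,
    )


@dataclass(frozen=True)
class HistogramDecomposition:
    """K-component Gaussian decomposition of a FRET population.

    ``areas`` are normalized component weights (sum to 1); multiplied by
    ``n_samples`` they give the peak areas on the count scale.  Components
    are reported in ascending center order and mapped onto folding states
    by :func:`default_state_labels`.
    """

    centers: np.ndarray
    widths: np.ndarray
    areas: np.ndarray
    n_samples: int
    log_likelihood: float
    goodness: dict = field(default_factory=dict)
    state_labels: tuple[str, ...] = ()

    def __post_init__(self):
        c = np.asarray(self.centers, dtype=float)
        w = np.asarray(self.widths, dtype=float)
        a = np.asarray(self.areas, dtype=float)
        if not (c.size == w.size == a.size):
            raise ValueError("centers, widths and areas must have equal length")
        if np.any(np.diff(c) < 0):
            raise ValueError("centers must be ascending")
        if np.any(w <= 0):
            raise ValueError("widths must be positive")
        if np.any(a < 0) or abs(a.sum() - 1.0) > 1e-6:
            raise ValueError("areas must be non-negative and sum to 1")
        labels = self.state_labels or default_state_labels(c.size)
        object.__setattr__(self, "centers", c)
        object.__setattr__(self, "widths", w)
        object.__setattr__(self, "areas", a / a.sum())
        object.__setattr__(self, "state_labels", tuple(labels))

    @property
    def n_components(self) -> int:
        return self.centers.size

    @property
    def state_assignment(self) -> dict[int, str]:
        return dict(enumerate(self.state_labels))

    def pdf(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return np.sum(
            self.areas * stats.norm.pdf(x[..., None], self.centers, self.widths), axis=-1
        )

    def to_dict(self) -> dict:
        return {
            "n_components": int(self.n_components),
            "centers": self.centers.tolist(),
            "widths": self.widths.tolist(),
            "areas": self.areas.tolist(),
            "n_samples": int(self.n_samples),
            "log_likelihood": float(self.log_likelihood),
            "goodness": self.goodness,
            "state_labels": list(self.state_labels),
        }


_LOG_2PI = float(np.log(2.0 * np.pi))


def _mixture_em(x, w, mu, sigma, width_bounds, anchors, anchor_tol, tol, max_iter, rng):
    """EM for a 1-D Gaussian mixture with width bounds and center anchors."""
    n = x.size
    ll_prev = -np.inf
    for _ in range(max_iter):
        z = (x[:, None] - mu) / sigma
        log_comp = (
            np.log(np.maximum(w, 1e-300))
            - 0.5 * z * z - np.log(sigma) - 0.5 * _LOG_2PI
        )
        ll_frame = logsumexp(log_comp, axis=1)
        ll = float(ll_frame.sum())
        resp = np.exp(log_comp - ll_frame[:, None])
        nk = resp.sum(axis=0)

        dead = nk < 1e-8
        if np.any(dead):
            if anchors is None:
                # re-seed dead components at random observations
                mu = mu.copy()
                mu[dead] = rng.choice(x, size=int(dead.sum()))
                sigma = np.full_like(sigma, max(x.std(), width_bounds[0]))
                w = np.full_like(w, 1.0 / w.size)
                ll_prev = -np.inf
                continue
            # anchored mode: park the component at its anchor with ~zero weight
            w = nk / n
            upd = ~dead
            mu = np.where(upd, np.where(nk > 0, resp.T @ x, 0) / np.maximum(nk, 1e-300), mu)
        else:
            w = nk / n
            mu = (resp.T @ x) / nk
        if anchors is not None:
            mu = np.clip(mu, anchors - anchor_tol, anchors + anchor_tol)
        var = (resp.T @ (x * x)) / np.maximum(nk, 1e-300) - mu**2
        sigma_new = np.sqrt(np.clip(var, width_bounds[0] ** 2, width_bounds[1] ** 2))
        sigma = np.where(nk >= 1e-8, sigma_new, sigma)

        if ll - ll_prev < tol and np.isfinite(ll_prev):
            return w, mu, sigma, ll, True
        ll_prev = ll
    return w, mu, sigma, ll_prev, False


def fit_gaussian_mixture(
    samples,
    n_components: int,
    *,
    seed: int | np.random.SeedSequence | None = 0,
    n_restarts: int = 5,
    width_bounds: tuple[float, float] = DEFAULT_WIDTH_BOUNDS,
    center_anchors: Sequence[float] | None = None,
    anchor_tol: float = 0.05,
    init: HistogramDecomposition | None = None,
    tol: float = 1e-8,
    max_iter: int = 500,
    method: str = "em",
    bin_width: float = 0.02,
    state_labels: Sequence[str] | None = None,
) -> HistogramDecomposition:
    """Decompose pooled FRET samples into ``n_components`` Gaussian peaks.

    ``method="em"`` (default) maximizes the sample likelihood directly;
    ``method="binned-lsq"`` fits the multipeak Gaussian curve to the binned
    histogram by weighted least squares, for parity with conventional
    curve-fitting analyses.  ``center_anchors`` (e.g. HMM state means)
    constrain each center to within ``anchor_tol`` of its anchor, which
    stabilizes four-component fits when one state is sparsely occupied.
    """
    x = np.clip(np.asarray(samples, dtype=float).ravel(), 0.0, 1.0)
    K = int(n_components)
    if K < 1:
        raise ValueError("n_components must be >= 1")
    if x.size < 20 * K:
        raise ValueError(f"need >= {20 * K} samples for {K} components, got {x.size}")
    anchors = None
    if center_anchors is not None:
        anchors = np.sort(np.asarray(center_anchors, dtype=float))
        if anchors.size != K:
            raise ValueError("center_anchors must have one entry per component")

    if method == "binned-lsq":
        return _fit_binned_lsq(x, K, width_bounds, anchors, bin_width, state_labels)
    if method != "em":
        raise ValueError(f"unknown method {method!r}")

    rng = np.random.default_rng(seed)
    best = None
    n_runs = 1 if init is not None else max(1, n_restarts)
    for run in range(n_runs):
        if init is not None:
            w0, mu0, s0 = init.areas.copy(), init.centers.copy(), init.widths.copy()
        elif anchors is not None and run == 0:
            w0 = np.full(K, 1.0 / K)
            mu0, s0 = anchors.copy(), np.full(K, 0.06)
        else:
            qs = (np.arange(K) + 0.5) / K
            mu0 = np.quantile(x, qs)
            if run > 0:
                mu0 = np.sort(np.clip(mu0 + rng.normal(0, 0.1, K), 0, 1))
            w0 = np.full(K, 1.0 / K)
            s0 = np.full(K, np.clip(x.std() / max(K, 1), *width_bounds))
        w, mu, sigma, ll, conv = _mixture_em(
            x, w0, mu0, s0, width_bounds, anchors, anchor_tol, tol, max_iter, rng
        )
        if best is None or ll > best[3]:
            best = (w, mu, sigma, ll, conv)

    w, mu, sigma, ll, conv = best
    order = np.argsort(mu, kind="stable")
    w, mu, sigma = w[order], mu[order], sigma[order]
    w = np.maximum(w, 0.0)
    w = w / w.sum()
    goodness = _binned_goodness(x, w, mu, sigma, bin_width)
    goodness["converged"] = bool(conv)
    return HistogramDecomposition(
        centers=mu,
        widths=sigma,
        areas=w,
        n_samples=x.size,
        log_likelihood=ll,
        goodness=goodness,
        state_labels=tuple(state_labels) if state_labels else default_state_labels(K),
    )


def _binned_goodness(x, w, mu, sigma, bin_width) -> dict:
    hist = build_histogram(x, bin_width=bin_width)
    centers = hist.centers
    expected = x.size * bin_width * np.sum(
        w * stats.norm.pdf(centers[:, None], mu, sigma), axis=1
    )
    resid = hist.counts - expected
    ss_tot = float(np.sum((hist.counts - hist.counts.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else np.nan
    return {"rmse": float(np.sqrt(np.mean(resid**2))), "r_squared": r2}


def _fit_binned_lsq(x, K, width_bounds, anchors, bin_width, state_labels):
    """Weighted least-squares multipeak fit to the binned histogram."""
    hist = build_histogram(x, bin_width=bin_width)
    centers = hist.centers
    counts = hist.counts.astype(float)
    weights = 1.0 / np.sqrt(np.maximum(counts, 1.0))  # Poisson-ish weighting

    def curve(params):
        amp = params[:K]
        mu = params[K : 2 * K]
        sig = params[2 * K :]
        return np.sum(amp * stats.norm.pdf(centers[:, None], mu, sig), axis=1)

    qs = (np.arange(K) + 0.5) / K
    mu0 = anchors if anchors is not None else np.quantile(x, qs)
    p0 = np.concatenate([np.full(K, x.size * bin_width / K), mu0, np.full(K, 0.06)])
    lo_mu = anchors - 0.05 if anchors is not None else np.zeros(K)
    hi_mu = anchors + 0.05 if anchors is not None else np.ones(K)
    bounds = (
        np.concatenate([np.zeros(K), lo_mu, np.full(K, width_bounds[0])]),
        np.concatenate([np.full(K, np.inf), hi_mu, np.full(K, width_bounds[1])]),
    )
    res = optimize.least_squares(
        lambda p: (curve(p) - counts) * weights, p0, bounds=bounds
    )
    amp, mu, sig = res.x[:K], res.x[K : 2 * K], res.x[2 * K :]
    order = np.argsort(mu, kind="stable")
    amp, mu, sig = amp[order], mu[order], sig[order]
    areas = amp / amp.sum()
    resid = curve(res.x) - counts
    ss_tot = float(np.sum((counts - counts.mean()) ** 2))
    goodness = {
        "rmse": float(np.sqrt(np.mean(resid**2))),
        "r_squared": 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else np.nan,
        "converged": bool(res.success),
    }
    return HistogramDecomposition(
        centers=mu,
        widths=sig,
        areas=areas,
        n_samples=x.size,
        log_likelihood=np.nan,
        goodness=goodness,
        state_labels=tuple(state_labels) if state_labels else default_state_labels(K),
    )


def state_fractions(decomposition: HistogramDecomposition) -> dict[str, float]:
    """Peak-area ratios as state occupancies, keyed by state label."""
    return {
        label: float(a)
        for label, a in zip(decomposition.state_labels, decomposition.areas)
    }


@dataclass
class ConditionFit:
    """A fitted condition: decomposition plus the per-molecule samples.

    Keeping the molecule-level samples enables molecule-resampling
    bootstraps for confidence intervals.
    """

    decomposition: HistogramDecomposition
    molecule_samples: list[np.ndarray]
    label: str = ""

    @property
    def pooled(self) -> np.ndarray:
        return np.concatenate(self.molecule_samples)


def fit_condition(
    molecule_samples: Sequence[np.ndarray],
    n_components: int,
    label: str = "",
    **fit_kw,
) -> ConditionFit:
    """Pool per-molecule samples and fit the mixture for one condition."""
    samples = [np.asarray(s, dtype=float) for s in molecule_samples if len(s)]
    if not samples:
        raise ValueError("no molecule samples supplied")
    dec = fit_gaussian_mixture(np.concatenate(samples), n_components, **fit_kw)
    return ConditionFit(decomposition=dec, molecule_samples=samples, label=label)


def _bootstrap_fractions(
    fit: ConditionFit, n_boot: int, rng: np.random.Generator, **fit_kw
) -> np.ndarray:
    """(n_boot, K) state fractions from molecule-level resampling.

    Each replicate resamples molecules with replacement, pools their
    samples, and refits starting from the point estimate (single run) so
    component identities stay aligned across replicates.
    """
    mols = fit.molecule_samples
    K = fit.decomposition.n_components
    out = np.empty((n_boot, K))
    fit_kw.setdefault("width_bounds", DEFAULT_WIDTH_BOUNDS)
    for b in range(n_boot):
        idx = rng.integers(0, len(mols), len(mols))
        pooled = np.concatenate([mols[i] for i in idx])
        dec = fit_gaussian_mixture(
            pooled,
            K,
            init=fit.decomposition,
            n_restarts=1,
            seed=rng,
            max_iter=100,
            tol=1e-5,
            **fit_kw,
        )
        out[b] = dec.areas
    return out


@dataclass
class TitrationResult:
    """Folded/unfolded fractions versus KCl concentration with CIs."""

    kcl_mM: np.ndarray
    fractions: np.ndarray  # (n_conditions, K); NaN rows mark failed fits
    ci_low: np.ndarray
    ci_high: np.ndarray
    state_labels: tuple[str, ...]
    fits: dict[float, ConditionFit]
    construct: str = ""

    @property
    def folded_fraction(self) -> np.ndarray:
        return self.fractions[:, -1]

    @property
    def unfolded_fraction(self) -> np.ndarray:
        return self.fractions[:, 0]

    def to_frame(self):
        import pandas as pd

        data = {"kcl_mM": self.kcl_mM}
        for j, lab in enumerate(self.state_labels):
            data[lab] = self.fractions[:, j]
            data[f"{lab}_lo"] = self.ci_low[:, j]
            data[f"{lab}_hi"] = self.ci_high[:, j]
        return pd.DataFrame(data)


def titration_curve(
    samples_by_kcl: Mapping[float, Sequence[np.ndarray]],
    n_components: int,
    *,
    n_boot: int = 200,
    seed: int | None = 0,
    ci_level: float = 0.95,
    construct: str = "",
    **fit_kw,
) -> TitrationResult:
    """State fractions across a K+ titration with bootstrap CIs.

    Conditions whose fit fails are reported as NaN rows rather than
    fabricated.  CIs are molecule-level bootstrap percentiles.
    """
    if len(samples_by_kcl) < 2:
        raise ValueError("a titration needs at least two conditions")
    kcl = np.array(sorted(samples_by_kcl), dtype=float)
    K = int(n_components)
    fractions = np.full((kcl.size, K), np.nan)
    ci_low = np.full((kcl.size, K), np.nan)
    ci_high = np.full((kcl.size, K), np.nan)
    fits: dict[float, ConditionFit] = {}
    rng = np.random.default_rng(seed)
    alpha = (1.0 - ci_level) / 2.0
    for i, c in enumerate(kcl):
        try:
            fit = fit_condition(samples_by_kcl[c], K, label=f"{c:g} mM", **fit_kw)
            boot = _bootstrap_fractions(
                fit,
                n_boot,
                rng,
                **{k: v for k, v in fit_kw.items() if k in ("center_anchors", "anchor_tol", "width_bounds")},
            )
        except (ValueError, RuntimeError):
            continue
        fits[float(c)] = fit
        fractions[i] = fit.decomposition.areas
        ci_low[i] = np.quantile(boot, alpha, axis=0)
        ci_high[i] = np.quantile(boot, 1.0 - alpha, axis=0)
    return TitrationResult(
        kcl_mM=kcl,
        fractions=fractions,
        ci_low=ci_low,
        ci_high=ci_high,
        state_labels=default_state_labels(K),
        fits=fits,
        construct=construct,
    )


@dataclass
class ComparisonResult:
    """Per-state occupancy change between two conditions (after - before)."""

    delta: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    state_labels: tuple[str, ...]
    before_fractions: np.ndarray
    after_fractions: np.ndarray

    @property
    def delta_folded(self) -> float:
        return float(self.delta[-1])

    @property
    def delta_unfolded(self) -> float:
        return float(self.delta[0])


def compare_conditions(
    before: ConditionFit,
    after: ConditionFit,
    *,
    n_boot: int = 200,
    seed: int | None = 0,
    ci_level: float = 0.95,
    **fit_kw,
) -> ComparisonResult:
    """Occupancy change per state with molecule-bootstrap CIs.

    Components are matched by canonical (ascending-center) order; helicase
    unwinding shows up as a negative change of the folded (highest) state
    and a positive change of the unfolded (lowest) state.
    """
    if before.decomposition.n_components != after.decomposition.n_components:
        raise ValueError(
            "cannot compare decompositions with different component counts: "
            f"{before.decomposition.n_components} vs {after.decomposition.n_components}"
        )
    rng = np.random.default_rng(seed)
    boot_b = _bootstrap_fractions(before, n_boot, rng, **fit_kw)
    boot_a = _bootstrap_fractions(after, n_boot, rng, **fit_kw)
    delta_boot = boot_a - boot_b
    alpha = (1.0 - ci_level) / 2.0
    return ComparisonResult(
        delta=after.decomposition.areas - before.decomposition.areas,
        ci_low=np.quantile(delta_boot, alpha, axis=0),
        ci_high=np.quantile(delta_boot, 1.0 - alpha, axis=0),
        state_labels=before.decomposition.state_labels,
        before_fractions=before.decomposition.areas,
        after_fractions=after.decomposition.areas,
    )
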