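"""Inference on fused-telomere count tables.

Observed-vs-expected chi-square goodness of fit against the random null,
Eu/Het aggregation, exact binomial testing of Y-ring excess, and maximum
likelihood estimation of the heterochromatin fusigenicity weight with a
bootstrap confidence interval.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Mapping

import numpy as np
from scipy import optimize, stats

from .fusion_simulator import CountTable
from .karyotype import CATEGORIES, EU_CATEGORIES, HET_CATEGORIES, KaryotypeConfig

__all__ = [
    "ChiSquareResult",
    "RingTestResult",
    "BiasEstimate",
    "StatsError",
    "chisq_gof",
    "aggregate_eu_het",
    "ring_excess_test",
    "estimate_bias",
    "holm_adjust",
]

W_CAP = 1e6  # bound on the fusigenicity weight for degenerate tables
W_FLOOR = 1e-6


class StatsError(ValueError):
    """Raised for inconsistent inputs to the statistical routines."""


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    df: int
    p_value: float
    per_category_contributions: Mapping[str, float]
    low_expected_warning: bool


@dataclass(frozen=True)
class RingTestResult:
    p_value: float
    observed_fraction: float
    expected_fraction: float
    y_fusion_count: int
    y_ring_count: int
    degenerate: bool


@dataclass(frozen=True)
class BiasEstimate:
    w_hat: float
    log_likelihood: float
    ci_low: float
    ci_high: float
    converged: bool
    capped: bool
    n_boot: int


def chisq_gof(
    observed: Mapping[str, int | float],
    expected_freq: Mapping[str, Fraction | float],
) -> ChiSquareResult:
    """Chi-square goodness of fit of observed category counts against fixed
    expected frequencies.

    Expected counts are ``N * freq_c`` with ``N`` the observed total;
    ``df = k - 1`` (the frequencies are fixed a priori by the karyotype, not
    estimated).  ``low_expected_warning`` is set when any expected count
    falls below 5.
    """
    if set(observed) != set(expected_freq):
        raise StatsError(
            f"category mismatch: {sorted(observed)} vs {sorted(expected_freq)}"
        )
    cats = [c for c in CATEGORIES if c in observed] or sorted(observed)
    obs = np.array([float(observed[c]) for c in cats])
    freq = np.array([float(expected_freq[c]) for c in cats])
    if (obs < 0).any():
        raise StatsError("observed counts must be non-negative")
    total = obs.sum()
    if total <= 0:
        raise StatsError("observed counts must sum to a positive total")
    if not math.isclose(freq.sum(), 1.0, abs_tol=1e-9):
        raise StatsError("expected frequencies must sum to 1")
    exp = total * freq
    bad = (exp == 0) & (obs > 0)
    if bad.any():
        raise StatsError(
            f"zero expected frequency with nonzero observed count: "
            f"{[c for c, flag in zip(cats, bad) if flag]}"
        )
    keep = exp > 0
    contributions = {
        c: float((o - e) ** 2 / e)
        for c, o, e, k in zip(cats, obs, exp, keep)
        if k
    }
    statistic = float(sum(contributions.values()))
    df = len(cats) - 1
    p_value = float(stats.chi2.sf(statistic, df)) if statistic > 0 else 1.0
    return ChiSquareResult(
        statistic=statistic,
        df=df,
        p_value=p_value,
        per_category_contributions=contributions,
        low_expected_warning=bool((exp[keep] < 5).any()),
    )


def aggregate_eu_het(
    counts: CountTable | Mapping[str, int | float | Fraction],
) -> dict[str, int | float | Fraction]:
    """Collapse per-category values into the Eu = A + XL and
    Het = XR + Fourth + Y groups; totals are preserved."""
    values = counts.ft_counts if isinstance(counts, CountTable) else counts
    eu = sum(values.get(c, 0) for c in EU_CATEGORIES)
    het = sum(values.get(c, 0) for c in HET_CATEGORIES)
    return {"Eu": eu, "Het": het}


def ring_excess_test(
    y_fusion_count: int,
    y_ring_count: int,
    null_fraction: Fraction | float,
) -> RingTestResult:
    """Exact binomial upper-tail test for an excess of YL-YS rings among
    Y-involving fusions against the null fraction (1/15 or 1/6)."""
    if not 0 <= y_ring_count <= y_fusion_count:
        raise StatsError("need 0 <= y_ring_count <= y_fusion_count")
    p0 = float(null_fraction)
    if not 0.0 <= p0 <= 1.0:
        raise StatsError("null_fraction must lie in [0, 1]")
    if y_fusion_count == 0:
        return RingTestResult(
            p_value=1.0,
            observed_fraction=float("nan"),
            expected_fraction=p0,
            y_fusion_count=0,
            y_ring_count=0,
            degenerate=True,
        )
    test = stats.binomtest(y_ring_count, y_fusion_count, p0, alternative="greater")
    return RingTestResult(
        p_value=float(test.pvalue),
        observed_fraction=y_ring_count / y_fusion_count,
        expected_fraction=p0,
        y_fusion_count=y_fusion_count,
        y_ring_count=y_ring_count,
        degenerate=False,
    )


class _PairLikelihood:
    """Composite multinomial likelihood for category FT counts.

    Fusion events are treated as independent draws from the weighted pair
    distribution p_ij ∝ w_i * w_j over the enumerated pair space (w for
    heterochromatin-associated telomeres, 1 otherwise), without a
    replacement-depletion correction.  The observable is the per-category
    FT count via the pair → category map.  Adequate well below 1 fusion
    per cell; :class:`_DepletionLikelihood` is the default otherwise.
    """

    def __init__(self, karyotype: KaryotypeConfig):
        telomeres = karyotype.telomeres
        self.cats = list(karyotype.categories)
        cat_index = {c: k for k, c in enumerate(self.cats)}
        het = np.array([t.het_associated for t in telomeres], dtype=int)
        n = len(telomeres)
        ii, jj = np.triu_indices(n, k=1)
        self.exponent = het[ii] + het[jj]  # 0, 1 or 2 powers of w per pair
        self.cat_matrix = np.zeros((len(ii), len(self.cats)))
        for row, (i, j) in enumerate(zip(ii, jj)):
            self.cat_matrix[row, cat_index[telomeres[i].category]] += 1
            self.cat_matrix[row, cat_index[telomeres[j].category]] += 1

    def category_fractions(self, w: float) -> np.ndarray:
        pw = np.power(float(w), self.exponent)
        pw = pw / pw.sum()
        return pw @ self.cat_matrix / 2.0

    def log_likelihood(self, w: float, obs: np.ndarray) -> float:
        f = self.category_fractions(w)
        mask = obs > 0
        if (f[mask] <= 0).any():
            return -np.inf
        return float(np.sum(obs[mask] * np.log(f[mask])))

    def fit(self, obs: np.ndarray) -> tuple[float, float, bool]:
        """Maximize over log w on [W_FLOOR, W_CAP]; returns (w_hat, ll, ok)."""
        res = optimize.minimize_scalar(
            lambda t: -self.log_likelihood(math.exp(t), obs),
            bounds=(math.log(W_FLOOR), math.log(W_CAP)),
            method="bounded",
            options={"xatol": 1e-10},
        )
        w_hat = float(math.exp(res.x))
        return w_hat, -float(res.fun), bool(res.success)


class _DepletionLikelihood:
    """Depletion-aware composite likelihood for category FT counts.

    Within a cell, events are drawn sequentially without replacement, so
    biased pairing (w > 1) depletes the heterochromatin-associated pool and
    later events are less Het-rich than the first.  Ignoring this biases the
    weight estimate downward by >10% at w = 5 with ~1 event/cell.

    Telomeres are grouped into (category, weight-class) types; an exact
    dynamic program over type-count states gives the expected per-category
    FT increment at each event index, and the truncated-Poisson event-count
    distribution weights the indices.  The observable is modelled as
    multinomial with the resulting mean category fractions (a composite
    likelihood: within-pair/within-cell covariance is ignored, which makes
    the bootstrap mildly conservative).
    """

    def __init__(self, karyotype: KaryotypeConfig, events_per_cell_mean: float):
        self.cats = list(karyotype.categories)
        cat_index = {c: k for k, c in enumerate(self.cats)}
        groups: dict[tuple[int, bool], int] = {}
        for t in karyotype.telomeres:
            key = (cat_index[t.category], t.het_associated)
            groups[key] = groups.get(key, 0) + 1
        self.type_cat = [k[0] for k in groups]
        self.type_het = [k[1] for k in groups]
        self.type_count = tuple(groups.values())
        self.max_events = karyotype.total_telomeres // 2
        # P(K >= j) for the Poisson event count truncated at max_events
        self.tail = stats.poisson.sf(
            np.arange(self.max_events) , events_per_cell_mean
        )  # tail[j-1] = P(K >= j), truncation only lumps mass at the max

    def category_fractions(self, w: float) -> np.ndarray:
        n_types = len(self.type_count)
        wt = np.array([w if h else 1.0 for h in self.type_het])
        pairs = [
            (s, t) for s in range(n_types) for t in range(s, n_types)
        ]
        expected = np.zeros(len(self.cats))
        states: dict[tuple[int, ...], float] = {self.type_count: 1.0}
        for j in range(1, self.max_events + 1):
            tail_j = float(self.tail[j - 1])
            if tail_j <= 0 or not states:
                break
            new_states: dict[tuple[int, ...], float] = {}
            for state, prob in states.items():
                weights = []
                for s, t in pairs:
                    if s == t:
                        m = state[s] * (state[s] - 1) / 2.0
                    else:
                        m = state[s] * state[t]
                    weights.append(m * wt[s] * wt[t])
                z = sum(weights)
                if z <= 0:
                    continue
                for (s, t), wgt in zip(pairs, weights):
                    if wgt <= 0:
                        continue
                    q = prob * wgt / z
                    expected[self.type_cat[s]] += q * tail_j
                    expected[self.type_cat[t]] += q * tail_j
                    nxt = list(state)
                    nxt[s] -= 1
                    nxt[t] -= 1
                    key = tuple(nxt)
                    new_states[key] = new_states.get(key, 0.0) + q
            states = new_states
        return expected / expected.sum()

    def log_likelihood(self, w: float, obs: np.ndarray) -> float:
        f = self.category_fractions(w)
        mask = obs > 0
        if (f[mask] <= 0).any():
            return -np.inf
        return float(np.sum(obs[mask] * np.log(f[mask])))

    def fit(self, obs: np.ndarray) -> tuple[float, float, bool]:
        res = optimize.minimize_scalar(
            lambda t: -self.log_likelihood(math.exp(t), obs),
            bounds=(math.log(W_FLOOR), math.log(W_CAP)),
            method="bounded",
            options={"xatol": 1e-8},
        )
        return float(math.exp(res.x)), -float(res.fun), bool(res.success)


def _grid_refit(
    log_fracs: np.ndarray, log_w: np.ndarray, obs: np.ndarray
) -> float:
    """MLE of log w over a precomputed grid with parabolic refinement."""
    ll = log_fracs @ obs
    i = int(np.argmax(ll))
    if 0 < i < len(log_w) - 1:
        y0, y1, y2 = ll[i - 1], ll[i], ll[i + 1]
        denom = y0 - 2 * y1 + y2
        if denom < 0:
            step = 0.5 * (y0 - y2) / denom
            return float(log_w[i] + step * (log_w[i + 1] - log_w[i]))
    return float(log_w[i])


def estimate_bias(
    counts: CountTable | Mapping[str, int],
    karyotype: KaryotypeConfig,
    *,
    n_boot: int = 1000,
    seed: int = 0,
    conf: float = 0.95,
    events_per_cell_mean: float | None = None,
    depletion_correction: bool = True,
) -> BiasEstimate:
    """Maximum-likelihood estimate of the heterochromatin fusigenicity
    weight ``w`` from a category count table, with a seeded percentile
    bootstrap confidence interval.

    By default the depletion-corrected likelihood is used, with the mean
    events per cell taken from ``events_per_cell_mean`` or, for a
    :class:`CountTable`, estimated as ``n_tfs / n_cells``.  Plain mappings
    without a known cell count fall back to the uncorrected single-event
    likelihood.

    Degenerate tables (all counts in one chromatin group) drive the
    likelihood monotone; the estimate is then capped at ``W_CAP`` (or
    ``W_FLOOR``) and flagged.
    """
    values = counts.ft_counts if isinstance(counts, CountTable) else dict(counts)
    if events_per_cell_mean is None and isinstance(counts, CountTable):
        if counts.n_cells > 0:
            events_per_cell_mean = counts.n_tfs / counts.n_cells
    if depletion_correction and events_per_cell_mean:
        lik = _DepletionLikelihood(karyotype, events_per_cell_mean)
    else:
        lik = _PairLikelihood(karyotype)
    if set(values) - set(lik.cats):
        raise StatsError(
            f"counts contain categories absent from the karyotype: "
            f"{sorted(set(values) - set(lik.cats))}"
        )
    obs = np.array([float(values.get(c, 0)) for c in lik.cats])
    total = int(obs.sum())
    if total <= 0:
        raise StatsError("need a positive total FT count")

    w_hat, ll, ok = lik.fit(obs)
    capped = w_hat >= W_CAP * (1 - 1e-3) or w_hat <= W_FLOOR * (1 + 1e-3)

    # Bootstrap on a precomputed log-fraction grid: a coarse global sweep
    # plus a fine window around the point estimate.
    log_w = np.unique(
        np.concatenate(
            [
                np.linspace(math.log(W_FLOOR), math.log(W_CAP), 61),
                np.linspace(math.log(w_hat) - 0.7, math.log(w_hat) + 0.7, 141),
            ]
        )
    )
    log_w = np.clip(log_w, math.log(W_FLOOR), math.log(W_CAP))
    log_w = np.unique(log_w)
    fracs = np.stack([lik.category_fractions(math.exp(t)) for t in log_w])
    with np.errstate(divide="ignore"):
        log_fracs = np.where(fracs > 0, np.log(np.maximum(fracs, 1e-300)), -1e30)

    rng = np.random.default_rng(seed)
    p_obs = obs / obs.sum()
    boots = np.empty(n_boot)
    for b in range(n_boot):
        resampled = rng.multinomial(total, p_obs).astype(float)
        boots[b] = math.exp(_grid_refit(log_fracs, log_w, resampled))
    alpha = 1.0 - conf
    ci_low, ci_high = np.quantile(boots, [alpha / 2, 1 - alpha / 2])
    ci_low = float(min(ci_low, w_hat))
    ci_high = float(max(ci_high, w_hat))
    return BiasEstimate(
        w_hat=w_hat,
        log_likelihood=ll,
        ci_low=ci_low,
        ci_high=ci_high,
        converged=ok,
        capped=capped,
        n_boot=n_boot,
    )


def holm_adjust(p_values: list[float]) -> list[float]:
    """Holm step-down adjustment of a family of p-values."""
    if not p_values:
        return []
    from statsmodels.stats.multitest import multipletests

    _, adjusted, _, _ = multipletests(p_values, method="holm")
    return [float(p) for p in adjusted]
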