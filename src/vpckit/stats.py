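"""Statistics layer: simulated-null permutation tests, causal power, sliding
ledger probabilities, cluster-based permutation on time-frequency maps, KS
comparison of MIP distributions, Holm-Bonferroni control, interaction linear
models and spike-rate summaries."""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import ndimage
from scipy import stats as scipy_stats
from statsmodels.stats.multitest import multipletests


# ---------------------------------------------------------------------------
# Multiple comparisons

def holm_bonferroni(pvals: np.ndarray, alpha: float = 0.05
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Step-down Holm correction; returns (corrected p, reject flags)."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return pvals, np.zeros(0, dtype=bool)
    if np.any((pvals < 0) | (pvals > 1)):
        raise ValueError("p-values outside [0, 1]")
    reject, p_corr, _, _ = multipletests(pvals, alpha=alpha, method="holm")
    return p_corr, reject


# ---------------------------------------------------------------------------
# Simulated-null permutation framework

@dataclass
class NullDistribution:
    """One category's simulated null with the observed statistic."""

    category: str
    samples: np.ndarray
    observed: float
    z: float
    p: float
    p_corrected: float = np.nan
    nboot: int = 0


def simulated_null_test(population: dict, observed: dict, nboot: int = 10_000,
                        replace: bool = False, statistic: str = "probability",
                        rng: np.random.Generator | int | None = None,
                        alpha: float = 0.05) -> dict:
    """Category-specific null test by simulated random sampling.

    ``population`` maps category -> member count N_c; ``observed`` maps
    category -> observation count n_c.  Each of ``nboot`` simulations draws
    n = sum(n_c) members from the pooled population (without replacement when
    the population is finite and unrepeatable) and computes the per-category
    statistic: occurrence probability (count / N_c) or sample proportion
    (count / n).  Observed values are compared against the simulated nulls to
    yield Z statistics and two-sided smoothed p-values, Holm-corrected across
    categories.
    """
    rng = np.random.default_rng(rng)
    cats = sorted(population)
    counts = np.array([population[c] for c in cats], dtype=int)
    n_obs = int(sum(observed.get(c, 0) for c in cats))
    if n_obs == 0:
        raise ValueError("no observations")
    if not replace and n_obs > counts.sum():
        raise ValueError("cannot draw more observations than population members")

    if replace:
        draws = rng.multinomial(n_obs, counts / counts.sum(), size=nboot)
    else:
        pool = np.repeat(np.arange(len(cats)), counts)
        draws = np.empty((nboot, len(cats)), dtype=int)
        for b in range(nboot):
            picked = rng.choice(pool, size=n_obs, replace=False)
            draws[b] = np.bincount(picked, minlength=len(cats))

    if statistic == "probability":
        null_stats = draws / counts[None, :]
        obs_stats = np.array([observed.get(c, 0) / population[c] for c in cats])
    elif statistic == "proportion":
        null_stats = draws / n_obs
        obs_stats = np.array([observed.get(c, 0) / n_obs for c in cats])
    else:
        raise ValueError("statistic must be 'probability' or 'proportion'")

    results = {}
    pvals = []
    for j, c in enumerate(cats):
        samples = null_stats[:, j]
        mu, sd = samples.mean(), samples.std(ddof=1)
        if sd == 0:
            import warnings
            warnings.warn(f"degenerate null for category {c}; p at boundary")
            z = 0.0
            p = 1.0
        else:
            z = (obs_stats[j] - mu) / sd
            lo = (np.sum(samples <= obs_stats[j]) + 1) / (nboot + 1)
            hi = (np.sum(samples >= obs_stats[j]) + 1) / (nboot + 1)
            p = min(1.0, 2.0 * min(lo, hi))
        results[c] = NullDistribution(category=c, samples=samples,
                                      observed=float(obs_stats[j]), z=float(z),
                                      p=float(p), nboot=nboot)
        pvals.append(p)
    p_corr, _ = holm_bonferroni(np.array(pvals), alpha=alpha)
    for c, pc in zip(cats, p_corr):
        results[c].p_corrected = float(pc)
    return results


# ---------------------------------------------------------------------------
# Causal power

@dataclass
class CausalTable:
    """Conditional-probability table of effect given candidate cause."""

    p_e_given_c: float       # P(e+|c+)
    p_e_given_not_c: float   # P(e+|c-)

    def __post_init__(self) -> None:
        for p in (self.p_e_given_c, self.p_e_given_not_c):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")


def causal_power(table: CausalTable | tuple) -> float:
    """CP = (P(e+|c+) - P(e+|c-)) / (1 - P(e+|c-)).

    Positive CP: the proposed cause raises the outcome probability more than
    the alternatives; CP = 1 when the cause guarantees the outcome.
    """
    if not isinstance(table, CausalTable):
        table = CausalTable(*table)
    if table.p_e_given_not_c >= 1.0:
        raise ZeroDivisionError("P(e+|c-) = 1 leaves causal power undefined")
    return (table.p_e_given_c - table.p_e_given_not_c) / (1.0 - table.p_e_given_not_c)


# ---------------------------------------------------------------------------
# Sliding ledger probabilities

def sliding_probability(ledger, window: int = 32, step: int = 1,
                        event_type: str = "VPC", task: str | None = "RW"
                        ) -> pd.DataFrame:
    """Local event probability (LEP) and local stimulation predominance (LSP)
    in sliding windows of ``window`` blocks, both normalized to their maxima.

    Returns one row per window with the raw and normalized values, the
    majority series type and phase.
    """
    blocks = ledger.blocks
    if task is not None:
        blocks = blocks[blocks.task == task]
    blocks = blocks.sort_values("block_id").reset_index(drop=True)
    if len(blocks) < window:
        raise ValueError(f"need at least {window} blocks, have {len(blocks)}")
    ev = ledger.events_of_type(event_type)
    has_event = blocks.block_id.isin(ev.block_id.unique() if len(ev) else []).to_numpy()
    is_stim = (blocks.condition != "NS").to_numpy()
    rows = []
    for i in range(0, len(blocks) - window + 1, step):
        sl = slice(i, i + window)
        sub = blocks.iloc[sl]
        rows.append({
            "window_start_block": int(sub.block_id.iloc[0]),
            "lep_raw": float(has_event[sl].mean()),
            "lsp_raw": float(is_stim[sl].mean()),
            "series": sub.series.mode().iloc[0],
            "series_phase": sub.series_phase.mode().iloc[0],
        })
    out = pd.DataFrame(rows)
    for col in ("lep", "lsp"):
        m = out[f"{col}_raw"].max()
        out[col] = out[f"{col}_raw"] / m if m > 0 else out[f"{col}_raw"]
    return out


def lep_lsp_correlation(sliding: pd.DataFrame) -> tuple[float, float]:
    """Pearson correlation of local event probability with stimulation
    predominance, with its p-value."""
    r, p = scipy_stats.pearsonr(sliding.lep, sliding.lsp)
    return float(r), float(p)


# ---------------------------------------------------------------------------
# Cluster-based permutation (Maris-Oostenveld style)

@dataclass
class Cluster:
    mask: np.ndarray
    t_sum: float
    p: float
    sign: int


def _t_maps(data: np.ndarray, groups: np.ndarray) -> np.ndarray:
    a = data[groups]
    b = data[~groups]
    na, nb = len(a), len(b)
    ma, mb = a.mean(0), b.mean(0)
    va, vb = a.var(0, ddof=1), b.var(0, ddof=1)
    sp = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    denom = np.sqrt(sp * (1 / na + 1 / nb))
    with np.errstate(invalid="ignore", divide="ignore"):
        t = (ma - mb) / denom
    return np.nan_to_num(t)


def _cluster_sums(t_map: np.ndarray, thresh: float) -> list[tuple[np.ndarray, float]]:
    out = []
    for sign in (1, -1):
        lab, n = ndimage.label(sign * t_map > thresh)
        for i in range(1, n + 1):
            mask = lab == i
            out.append((mask, float(t_map[mask].sum())))
    return out


def cluster_permutation(grams_a: np.ndarray, grams_b: np.ndarray,
                        nboot: int = 10_000, alpha: float = 0.05,
                        cluster_alpha: float = 0.05,
                        rng: np.random.Generator | int | None = None
                        ) -> list[Cluster]:
    """Cluster-based permutation test on stacks of time-frequency maps.

    Pointwise two-sample t-maps are thresholded at the ``cluster_alpha``
    two-sided critical value, contiguous supra-threshold tiles are summed
    (Tsum, separately per sign), and observed cluster masses are referred to
    the permutation distribution of the maximum absolute cluster mass.
    Returns the clusters significant at ``alpha``.
    """
    rng = np.random.default_rng(rng)
    a = np.asarray(grams_a, dtype=float)
    b = np.asarray(grams_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups need at least one sample")
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 samples per group")
    data = np.concatenate([a, b], axis=0)
    n = len(data)
    groups = np.zeros(n, dtype=bool)
    groups[: len(a)] = True
    df = n - 2
    thresh = scipy_stats.t.ppf(1 - cluster_alpha / 2, df)

    observed = _cluster_sums(_t_maps(data, groups), thresh)
    if not observed:
        return []
    null_max = np.empty(nboot)
    for i in range(nboot):
        perm = rng.permutation(groups)
        sums = _cluster_sums(_t_maps(data, perm), thresh)
        null_max[i] = max((abs(s) for _, s in sums), default=0.0)
    out = []
    for mask, t_sum in observed:
        p = (1 + np.sum(null_max >= abs(t_sum))) / (nboot + 1)
        if p <= alpha:
            out.append(Cluster(mask=mask, t_sum=t_sum, p=float(p),
                               sign=1 if t_sum > 0 else -1))
    return sorted(out, key=lambda c: -abs(c.t_sum))


# ---------------------------------------------------------------------------
# KS comparison of MIP-type distributions

def ks_compare_mip(codes_a: np.ndarray, codes_b: np.ndarray,
                   smooth: bool = True, grid_size: int = 512
                   ) -> tuple[float, float]:
    """Two-sample KS statistic between integer-coded MIP-type distributions.

    The discrete type frequencies are smoothed with a Gaussian kernel
    (Silverman bandwidth) before comparing CDFs; with fewer than 5 samples per
    state (or degenerate samples) the unsmoothed empirical CDFs are used.
    """
    a = np.asarray(codes_a, dtype=float)
    b = np.asarray(codes_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("need samples in both states")
    use_smooth = smooth and len(a) >= 5 and len(b) >= 5 \
        and a.std() > 0 and b.std() > 0
    if not use_smooth:
        if smooth and (len(a) < 5 or len(b) < 5):
            import warnings
            warnings.warn("fewer than 5 MIP samples; using empirical CDFs")
        res = scipy_stats.ks_2samp(a, b)
        return float(res.statistic), float(res.pvalue)
    kde_a = scipy_stats.gaussian_kde(a, bw_method="silverman")
    kde_b = scipy_stats.gaussian_kde(b, bw_method="silverman")
    lo = min(a.min(), b.min()) - 3 * max(kde_a.factor * a.std(), kde_b.factor * b.std())
    hi = max(a.max(), b.max()) + 3 * max(kde_a.factor * a.std(), kde_b.factor * b.std())
    grid = np.linspace(lo, hi, grid_size)
    pa = kde_a(grid)
    pb = kde_b(grid)
    cdf_a = np.cumsum(pa) / pa.sum()
    cdf_b = np.cumsum(pb) / pb.sum()
    ks = float(np.max(np.abs(cdf_a - cdf_b)))
    en = np.sqrt(len(a) * len(b) / (len(a) + len(b)))
    p = float(scipy_stats.kstwobign.sf(max(0.0, (en + 0.12 + 0.11 / en) * ks)))
    return ks, p


# ---------------------------------------------------------------------------
# Interaction linear models

@dataclass
class ModelFit:
    params: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    interaction_tests: pd.DataFrame
    result: object = field(repr=False, default=None)


def _center_dichotomous(series: pd.Series) -> np.ndarray:
    levels = sorted(pd.unique(series))
    if len(levels) != 2:
        raise ValueError(f"factor has {len(levels)} levels; need exactly 2")
    return np.where(series == levels[1], 0.5, -0.5)


def fit_interaction_model(data: pd.DataFrame, response: str,
                          factors: list[str], covariates: list[str] = (),
                          interactions: list[tuple[str, ...]] = ()) -> ModelFit:
    """OLS fit of a design with centered dichotomous factors and interactions.

    Factors are coded -0.5 / +0.5 (levels in sorted order); interaction
    columns are products of the coded factors; covariates enter as given
    (dichotomous covariates such as animal identity are also center-coded).
    Raises on rank deficiency, naming the aliased terms.
    """
    cols = {}
    for f in factors:
        cols[f] = _center_dichotomous(data[f])
    for c in covariates:
        vals = data[c]
        if vals.dtype == object or len(pd.unique(vals)) == 2:
            cols[c] = _center_dichotomous(vals)
        else:
            cols[c] = np.asarray(vals, dtype=float)
    for terms in interactions:
        name = ":".join(terms)
        prod = np.ones(len(data))
        for t in terms:
            prod = prod * cols[t]
        cols[name] = prod
    X = pd.DataFrame(cols, index=data.index)
    X = sm.add_constant(X)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        raise ValueError(f"rank-deficient design; aliased among {list(X.columns)}")
    fit = sm.OLS(np.asarray(data[response], dtype=float), X).fit()
    inter_rows = []
    for terms in interactions:
        name = ":".join(terms)
        ft = fit.f_test(f"{name} = 0")
        inter_rows.append({"term": name, "F": float(ft.fvalue),
                           "p": float(ft.pvalue), "t": float(fit.tvalues[name])})
    return ModelFit(params=fit.params, tvalues=fit.tvalues, pvalues=fit.pvalues,
                    interaction_tests=pd.DataFrame(inter_rows), result=fit)


# ---------------------------------------------------------------------------
# Spike-rate summaries

def spike_rate_summary(spikes: list, condition_epochs: dict,
                       effective_lengths: dict | None = None,
                       alpha: float = 0.05) -> pd.DataFrame:
    """Per-area normalized firing rates across conditions.

    ``condition_epochs`` maps condition -> list of (t0, t1) 1 s epochs;
    ``effective_lengths`` optionally maps condition -> array of usable seconds
    per epoch (after artifact excision).  Each unit's rate is normalized to
    its pre-condition mean; units absent in the pre condition are excluded.
    Per area and condition a one-sample t-test of the unit rates against 1
    is reported, Holm-corrected across areas within each condition.
    """
    rows = []
    for u in spikes:
        times = np.asarray(u["times"])
        rates = {}
        for cond, epochs in condition_epochs.items():
            eff = None if effective_lengths is None else effective_lengths.get(cond)
            vals = []
            for k, (t0, t1) in enumerate(epochs):
                n = np.sum((times >= t0) & (times < t1))
                div = (t1 - t0) if eff is None else eff[k]
                vals.append(n / div if div > 0 else np.nan)
            rates[cond] = np.nanmean(vals) if vals else np.nan
        pre = rates.get("pre", np.nan)
        if not np.isfinite(pre) or pre <= 0:
            continue
        for cond, r in rates.items():
            rows.append({"unit": u["unit"], "area": u["area"], "condition": cond,
                         "normalized_rate": r / pre})
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    out = []
    for cond, grp_c in df.groupby("condition"):
        stats_rows = []
        for area, grp in grp_c.groupby("area"):
            vals = grp.normalized_rate.dropna()
            if len(vals) >= 2 and vals.std() > 0:
                t, p = scipy_stats.ttest_1samp(vals, 1.0)
            else:
                t, p = np.nan, np.nan
            stats_rows.append({"condition": cond, "area": area,
                               "mean_rate": float(vals.mean()), "n_units": len(vals),
                               "t": float(t), "p": float(p)})
        ps = np.array([r["p"] for r in stats_rows])
        finite = np.isfinite(ps)
        p_corr = np.full(len(ps), np.nan)
        if finite.any():
            p_corr[finite], _ = holm_bonferroni(ps[finite], alpha=alpha)
        for r, pc in zip(stats_rows, p_corr):
            r["p_corrected"] = float(pc)
            out.append(r)
    return pd.DataFrame(out)
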