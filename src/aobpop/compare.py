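"""Population summaries and estrus vs. non-estrus hypothesis tests.

Covers per-stimulus responder fractions and mean magnitudes, the min-of-four-
tails binomial exact test for differences in responder counts, two-group
Kruskal-Wallis tests on response magnitudes, a two-way (stimulus x state)
ANOVA, binomial comparisons of receptive-field pattern frequencies, and
Bonferroni thresholds for each test family.

The binomial exact test follows a deliberately sensitive convention: under
the pooled response probability it evaluates the upper and lower tail for
each state's count and reports the smallest of the four probabilities,
without doubling. This is not a standard two-sided test; treat the resulting
p-values accordingly (the caveat is carried in output metadata).
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .patterns import PatternRegistry, PatternResult
from .quantify import ResponseMatrix, kruskal_p

__all__ = [
    "summarize_population",
    "binomial_exact_state_test",
    "magnitude_state_test",
    "magnitude_state_table",
    "responder_fraction_table",
    "two_way_anova",
    "pattern_frequency_state_test",
    "bonferroni_threshold",
    "rank_tukey_kramer",
]

BINOMIAL_CAVEAT = ("min of four binomial tail probabilities without doubling; "
                   "a sensitive, nonstandard convention")


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Family-wise threshold alpha/m (full precision; round only for display)."""
    if m < 1:
        raise ValueError("family size m must be >= 1")
    return alpha / m


def summarize_population(matrix: ResponseMatrix) -> dict:
    """Per-stimulus responder percentages by sign, mean magnitude +/- SE, and breadth.

    Returns a dict with a ``per_stimulus`` DataFrame (percent_increase,
    percent_decrease, mean_magnitude, sem) and an ``effective_counts`` Series
    (histogram over the number of significant responses per unit, 0-11).
    """
    mags = matrix.magnitudes
    sig = matrix.significant
    n = matrix.n_units
    inc = (sig & (mags > 0)).sum(axis=0) / n * 100.0
    dec = (sig & (mags <= 0)).sum(axis=0) / n * 100.0
    per_stim = pd.DataFrame({
        "percent_increase": inc,
        "percent_decrease": dec,
        "percent_responding": sig.mean(axis=0) * 100.0,
        "mean_magnitude": mags.mean(axis=0),
        "sem": mags.sem(axis=0),
    })
    counts = matrix.effective_stimulus_counts()
    hist = counts.value_counts().reindex(range(len(matrix.stimuli) + 1), fill_value=0)
    hist.index.name = "n_effective_stimuli"
    return {"per_stimulus": per_stim, "effective_counts": hist, "n_units": n}


def binomial_exact_state_test(k1: int, n1: int, k2: int, n2: int) -> float:
    """Min-of-four-tails binomial p for a difference in responder counts.

    Under the pooled rate p = (k1+k2)/(n1+n2), returns the smallest of
    P(X1>=k1), P(X1<=k1), P(X2>=k2), P(X2<=k2) with Xi ~ Binomial(ni, p).
    """
    for k, n in ((k1, n1), (k2, n2)):
        if n <= 0:
            raise ValueError("group sizes must be positive")
        if not 0 <= k <= n:
            raise ValueError("counts must satisfy 0 <= k <= n")
    p_hat = (k1 + k2) / (n1 + n2)
    tails = [
        stats.binom.sf(k1 - 1, n1, p_hat),   # P(X1 >= k1)
        stats.binom.cdf(k1, n1, p_hat),      # P(X1 <= k1)
        stats.binom.sf(k2 - 1, n2, p_hat),   # P(X2 >= k2)
        stats.binom.cdf(k2, n2, p_hat),      # P(X2 <= k2)
    ]
    return float(min(tails))


def magnitude_state_test(matrix: ResponseMatrix, stimulus: str) -> float:
    """Two-group Kruskal-Wallis p comparing one stimulus's magnitudes across states."""
    mags = matrix.magnitudes[stimulus]
    est = mags[matrix.states == "estrus"].to_numpy()
    non = mags[matrix.states == "non_estrus"].to_numpy()
    if est.size == 0 or non.size == 0:
        raise ValueError("both reproductive states must be represented")
    return kruskal_p(est, non)


def magnitude_state_table(matrix: ResponseMatrix, alpha: float = 0.05) -> pd.DataFrame:
    """Per-stimulus magnitude comparison across states, Bonferroni-corrected at alpha/11."""
    m = len(matrix.stimuli)
    thr = bonferroni_threshold(alpha, m)
    rows = []
    for stim in matrix.stimuli:
        mags = matrix.magnitudes[stim]
        rows.append({
            "stimulus": stim,
            "mean_estrus": float(mags[matrix.states == "estrus"].mean()),
            "mean_non_estrus": float(mags[matrix.states == "non_estrus"].mean()),
            "p_value": magnitude_state_test(matrix, stim),
            "bonferroni_threshold": thr,
        })
    out = pd.DataFrame(rows)
    out["significant"] = out["p_value"] < thr
    return out


def responder_fraction_table(matrix: ResponseMatrix, alpha: float = 0.05) -> pd.DataFrame:
    """Per-stimulus responder-fraction comparison across states (binomial exact test)."""
    m = len(matrix.stimuli)
    thr = bonferroni_threshold(alpha, m)
    est = matrix.states == "estrus"
    n1, n2 = int(est.sum()), int((~est).sum())
    rows = []
    for stim in matrix.stimuli:
        sig = matrix.significant[stim]
        k1 = int(sig[est].sum())
        k2 = int(sig[~est].sum())
        rows.append({
            "stimulus": stim,
            "percent_estrus": 100.0 * k1 / n1,
            "percent_non_estrus": 100.0 * k2 / n2,
            "n_estrus": n1, "n_non_estrus": n2,
            "p_value": binomial_exact_state_test(k1, n1, k2, n2),
            "bonferroni_threshold": thr,
        })
    out = pd.DataFrame(rows)
    out["significant"] = out["p_value"] < thr
    out.attrs["caveat"] = BINOMIAL_CAVEAT
    return out


def two_way_anova(matrix: ResponseMatrix) -> dict:
    """Two-way ANOVA (stimulus x state, full model with interaction) on magnitudes.

    Uses type-II sums of squares, appropriate for the unbalanced state group
    sizes. Returns the three p-values plus the ANOVA table.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    tidy = matrix.to_tidy()
    if tidy["stimulus"].nunique() < 2 or tidy["state"].nunique() < 2:
        raise ValueError("both factors need at least two levels")
    model = smf.ols("magnitude ~ C(stimulus) * C(state)", data=tidy).fit()
    table = sm.stats.anova_lm(model, typ=2)
    return {
        "p_stimulus": float(table.loc["C(stimulus)", "PR(>F)"]),
        "p_state": float(table.loc["C(state)", "PR(>F)"]),
        "p_interaction": float(table.loc["C(stimulus):C(state)", "PR(>F)"]),
        "table": table,
    }


def pattern_frequency_state_test(counts_est: pd.Series, n_est: int,
                                 counts_non: pd.Series, n_non: int,
                                 registry: PatternRegistry,
                                 shuffle_results_est: dict[str, PatternResult] | None = None,
                                 shuffle_results_non: dict[str, PatternResult] | None = None,
                                 alpha: float = 0.05) -> pd.DataFrame:
    """Binomial comparison of pattern frequencies across states, per registry pattern.

    Bonferroni thresholds are per group family (alpha over the family size,
    16 basic and 12 adjusted by default). Per-state overrepresentation flags
    from the column-shuffle test are carried through when provided.
    """
    rows = []
    for p in registry:
        k1, k2 = int(counts_est[p.id]), int(counts_non[p.id])
        thr = bonferroni_threshold(alpha, registry.family_size(p.group))
        row = {
            "pattern": p.id, "group": p.group,
            "freq_estrus": k1 / n_est, "freq_non_estrus": k2 / n_non,
            "count_estrus": k1, "count_non_estrus": k2,
            "p_value": binomial_exact_state_test(k1, n_est, k2, n_non),
            "bonferroni_threshold": thr,
        }
        if shuffle_results_est is not None:
            row["overrep_estrus"] = shuffle_results_est[p.id].p_value < alpha
        if shuffle_results_non is not None:
            row["overrep_non_estrus"] = shuffle_results_non[p.id].p_value < alpha
        rows.append(row)
    out = pd.DataFrame(rows)
    out["significant"] = out["p_value"] < out["bonferroni_threshold"]
    out["significant_uncorrected"] = out["p_value"] < alpha
    out.attrs["caveat"] = BINOMIAL_CAVEAT
    return out


def rank_tukey_kramer(matrix: ResponseMatrix, alpha: float = 0.05) -> pd.DataFrame:
    """Pairwise stimulus-magnitude comparisons on rank means, Tukey-Kramer corrected.

    A rank-based follow-up to an 11-group Kruskal-Wallis test: magnitudes
    from all stimuli are jointly ranked, and each stimulus pair is compared
    on mean ranks, with uncorrected normal-approximation p-values and
    Tukey-Kramer (studentized range, infinite df) corrected ones.
    """
    mags = matrix.magnitudes
    stimuli = matrix.stimuli
    long = mags.stack()
    ranks = stats.rankdata(long.to_numpy())
    long_ranks = pd.Series(ranks, index=long.index)
    big_n = long.size
    # tie-corrected rank variance
    _, counts = np.unique(long.to_numpy(), return_counts=True)
    tie_term = (counts**3 - counts).sum() / (big_n - 1) / 12.0
    s2 = big_n * (big_n + 1) / 12.0 - tie_term

    group_means = {s: float(long_ranks.xs(s, level=1).mean()) for s in stimuli}
    group_n = {s: int(long_ranks.xs(s, level=1).size) for s in stimuli}
    k = len(stimuli)
    rows = []
    for a, b in combinations(stimuli, 2):
        diff = group_means[a] - group_means[b]
        se = np.sqrt(s2 * (1.0 / group_n[a] + 1.0 / group_n[b]))
        z = diff / se
        p_unc = 2.0 * stats.norm.sf(abs(z))
        q = abs(diff) / (se / np.sqrt(2.0))
        p_tk = float(stats.studentized_range.sf(q, k, np.inf))
        rows.append({"stim_a": a, "stim_b": b, "rank_mean_diff": diff,
                     "p_uncorrected": float(p_unc), "p_tukey_kramer": p_tk})
    out = pd.DataFrame(rows)
    out["significant_corrected"] = out["p_tukey_kramer"] < alpha
    out["significant_uncorrected"] = out["p_uncorrected"] < alpha
    return out
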