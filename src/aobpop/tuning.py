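"""Per-unit tuning metrics and their estrus vs. non-estrus comparisons.

Metrics
-------
* **Preference index** PI_AB = (R_A - R_B)/(R_A + R_B) on *rectified*
  responses (negatives set to 0), bounded in [-1, 1]; a unit enters the pair
  only if it responds significantly to at least one of the two stimuli, and
  is excluded when both rectified responses are 0.
* **Lifetime sparseness** S = [1 - (sum|r_i|/N)^2 / (sum r_i^2 / N)] / (1 - 1/N),
  0 for uniform responses, 1 for a response to a single stimulus.
* **Triangle coordinates / selectivity index** for a stimulus triplet:
  rectified responses are normalized to sum 1 and placed in a 2-simplex via
  three unit vectors from the centre to the vertices;
  Si = sqrt((a-m)^2 + (b-m)^2 + (c-m)^2) / sqrt(2/3) with m = 1/3 equals the
  distance of the point from the centre (0 = centre, 1 = a vertex).

State comparisons use a label-reassignment permutation test for mean
preference indices and a two-group Kruskal-Wallis test for pairwise
selectivity (|PI|).
"""

from __future__ import annotations

from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .quantify import ResponseMatrix, kruskal_p
from .stimuli import PANEL_TOKENS, STRAINS, MALE_STATUSES

__all__ = [
    "preference_index",
    "stimulus_pairs",
    "pair_preference_table",
    "mean_pairwise_preferences",
    "cross_state_preference_correlation",
    "preference_state_test",
    "lifetime_sparseness",
    "triangle_coordinates",
    "selectivity_index",
    "pairwise_selectivity_compare",
    "selectivity_comparison_table",
    "default_state_comparisons",
]

#: Triangle vertex directions: first stimulus at the top, then counter-clockwise.
TRIANGLE_ANGLES = (90.0, 210.0, 330.0)


def rectify(values) -> np.ndarray:
    return np.maximum(np.asarray(values, dtype=float), 0.0)


def preference_index(r_a: float, r_b: float) -> float | None:
    """PI_AB on rectified responses; ``None`` when both rectify to 0 (excluded)."""
    a, b = max(float(r_a), 0.0), max(float(r_b), 0.0)
    if a + b == 0.0:
        return None
    return (a - b) / (a + b)


def stimulus_pairs(stimuli: Sequence[str] = PANEL_TOKENS) -> list[tuple[str, str]]:
    """All unordered stimulus pairs (55 for the canonical panel)."""
    return list(combinations(stimuli, 2))


def pair_preference_table(matrix: ResponseMatrix,
                          pairs: Sequence[tuple[str, str]] | None = None) -> pd.DataFrame:
    """Long table of per-unit preference indices with inclusion flags.

    Columns: unit, stim_a, stim_b, pi, included, state. Inclusion requires a
    significant response to at least one of the pair; a pair whose rectified
    responses are both 0 is excluded even if nominally significant (a
    significant suppression rectifies to 0).
    """
    pairs = list(pairs) if pairs is not None else stimulus_pairs(matrix.stimuli)
    mags = matrix.magnitudes
    sig = matrix.significant
    states = matrix.states
    rows = []
    for a, b in pairs:
        ra = rectify(mags[a].to_numpy())
        rb = rectify(mags[b].to_numpy())
        denom = ra + rb
        with np.errstate(invalid="ignore"):
            pi = np.where(denom > 0, (ra - rb) / np.where(denom > 0, denom, 1.0), np.nan)
        included = (sig[a] | sig[b]).to_numpy() & (denom > 0)
        rows.append(pd.DataFrame({
            "unit": mags.index, "stim_a": a, "stim_b": b,
            "pi": pi, "included": included, "state": states.to_numpy(),
        }))
    return pd.concat(rows, ignore_index=True)


def mean_pairwise_preferences(matrix: ResponseMatrix) -> pd.DataFrame:
    """Mean preference index per stimulus pair and reproductive state.

    Returns one row per (pair, state) with the mean PI over included units
    and the unit count; a pair with no included units in a state carries NaN
    and n = 0.
    """
    table = pair_preference_table(matrix)
    inc = table.loc[table["included"]]
    grouped = inc.groupby(["stim_a", "stim_b", "state"])["pi"].agg(["mean", "count"])
    grouped = grouped.rename(columns={"mean": "mean_pi", "count": "n"})
    # reindex to the full pair x state grid so undefined pairs are explicit
    full = pd.MultiIndex.from_tuples(
        [(a, b, s) for a, b in stimulus_pairs(matrix.stimuli)
         for s in ("non_estrus", "estrus")],
        names=["stim_a", "stim_b", "state"],
    )
    out = grouped.reindex(full)
    out["n"] = out["n"].fillna(0).astype(int)
    return out.reset_index()


def cross_state_preference_correlation(matrix: ResponseMatrix) -> dict:
    """Pearson correlation of the 55 mean preference indices across states.

    Reported twice: over all pairs defined in both states, and over the
    complete 55-pair grid (identical unless some pair lacks included units).
    """
    means = mean_pairwise_preferences(matrix)
    wide = means.pivot(index=["stim_a", "stim_b"], columns="state", values="mean_pi")
    both = wide.dropna()
    cc, p = stats.pearsonr(both["estrus"], both["non_estrus"])
    return {
        "cc": float(cc), "p_value": float(p), "n_pairs": int(len(both)),
        "n_pairs_total": int(len(wide)),
        "all_pairs_defined": bool(len(both) == len(wide)),
    }


def preference_state_test(matrix: ResponseMatrix, pair: tuple[str, str],
                          n_shuffles: int = 100_000,
                          seed: int | np.random.Generator | None = None,
                          tail: str = "ge") -> dict:
    """State-reassignment permutation test for one pair's mean preference index.

    The observed statistic is the absolute difference between the estrus and
    non-estrus mean PIs over included units. Each shuffle randomly reassigns
    the included units to the two states (group sizes preserved) and
    recomputes the statistic; p is the fraction of shuffled statistics >=
    observed (``tail='gt'`` for a strict tail).
    """
    if tail not in ("ge", "gt"):
        raise ValueError("tail must be 'ge' or 'gt'")
    table = pair_preference_table(matrix, pairs=[tuple(pair)])
    inc = table.loc[table["included"]]
    v = inc["pi"].to_numpy(dtype=float)
    is_est = (inc["state"] == "estrus").to_numpy()
    n1, n0 = int(is_est.sum()), int((~is_est).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError(f"pair {pair}: one state has no included units")
    observed = abs(v[is_est].mean() - v[~is_est].mean())

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    total = v.sum()
    n = v.size
    null = np.empty(n_shuffles)
    batch = max(1, min(n_shuffles, 20_000_000 // max(n, 1)))
    done = 0
    while done < n_shuffles:
        b = min(batch, n_shuffles - done)
        order = np.argsort(rng.random((b, n)), axis=1)[:, :n1]
        s1 = v[order].sum(axis=1)
        null[done:done + b] = np.abs(s1 / n1 - (total - s1) / n0)
        done += b
    p = float((null >= observed).mean() if tail == "ge" else (null > observed).mean())
    return {"pair": tuple(pair), "observed_abs_diff": float(observed),
            "p_value": p, "n_estrus": n1, "n_non_estrus": n0,
            "n_shuffles": n_shuffles}


# ---------------------------------------------------------------------------
# Sparseness and selectivity


def lifetime_sparseness(r: Sequence[float]) -> float:
    """Lifetime sparseness of a per-stimulus response vector (0 uniform, 1 one-hot).

    Computed on raw magnitudes; the absolute value and square inside the
    formula handle negative responses. An all-zero vector is defined as 0
    (the uniform limit).
    """
    r = np.asarray(r, dtype=float)
    n = r.size
    if n < 2:
        raise ValueError("sparseness needs at least two stimuli")
    sum_sq = float(np.sum(r * r))
    if sum_sq == 0.0:
        return 0.0
    mean_abs = float(np.sum(np.abs(r))) / n
    return (1.0 - mean_abs**2 / (sum_sq / n)) / (1.0 - 1.0 / n)


def _triangle_vertices() -> np.ndarray:
    ang = np.deg2rad(TRIANGLE_ANGLES)
    return np.column_stack([np.cos(ang), np.sin(ang)])


def triangle_coordinates(a: float, b: float, c: float) -> tuple[float, float] | None:
    """2-D triangle-plot position of a rectified response triplet.

    The triplet is rectified and normalized to weights summing to 1; the
    point is the weight-combination of three unit vectors from the centre to
    the vertices (first stimulus at the top). ``None`` when all three
    rectified responses are 0 (excluded).
    """
    w = rectify([a, b, c])
    total = w.sum()
    if total == 0.0:
        return None
    w = w / total
    xy = w @ _triangle_vertices()
    return float(xy[0]), float(xy[1])


def selectivity_index(a: float, b: float, c: float) -> float | None:
    """Normalized distance from the triangle centre, in [0, 1]; ``None`` if excluded."""
    w = rectify([a, b, c])
    total = w.sum()
    if total == 0.0:
        return None
    w = w / total
    m = 1.0 / 3.0
    d = np.sqrt(2.0 / 3.0)
    return float(np.sqrt(np.sum((w - m) ** 2)) / d)


def unit_metrics(matrix: ResponseMatrix) -> pd.DataFrame:
    """Per-unit tidy metrics table: sparseness plus per-strain virility selectivity."""
    mags = matrix.magnitudes
    rows = []
    for uid, row in mags.iterrows():
        entry = {"unit": uid, "state": matrix.states[uid],
                 "sparseness": lifetime_sparseness(row.to_numpy())}
        for strain in STRAINS:
            triplet = [row[f"M_{strain}_{st}"] for st in MALE_STATUSES]
            entry[f"selectivity_{strain}"] = selectivity_index(*triplet)
        rows.append(entry)
    return pd.DataFrame(rows).set_index("unit")


# ---------------------------------------------------------------------------
# Pairwise selectivity (|PI|) comparisons


def pairwise_selectivity_compare(matrix: ResponseMatrix, pair: tuple[str, str]) -> dict:
    """Mean |PI| per state for one pair, with a two-group Kruskal-Wallis p."""
    table = pair_preference_table(matrix, pairs=[tuple(pair)])
    inc = table.loc[table["included"]]
    out: dict = {"stim_a": pair[0], "stim_b": pair[1]}
    groups = {}
    for state in ("non_estrus", "estrus"):
        vals = inc.loc[inc["state"] == state, "pi"].abs().to_numpy()
        groups[state] = vals
        out[f"selectivity_{state}"] = float(vals.mean()) if vals.size else float("nan")
        out[f"n_{state}"] = int(vals.size)
    if groups["estrus"].size and groups["non_estrus"].size:
        out["p_value"] = kruskal_p(groups["estrus"], groups["non_estrus"])
    else:
        out["p_value"] = float("nan")
    return out


def default_state_comparisons() -> list[dict]:
    """The 23 ethologically grouped pairwise comparisons (by comparison type)."""
    comps: list[dict] = [{
        "type": "female_vs_female", "pair": ("F_ICR_EST", "F_ICR_NON_EST"),
    }]
    for male in ("M_ICR_DOM", "M_ICR_NAIVE"):
        for fem in ("F_ICR_EST", "F_ICR_NON_EST"):
            comps.append({"type": "male_vs_female", "pair": (male, fem)})
    for strain in STRAINS:
        for s1, s2 in combinations(MALE_STATUSES, 2):
            comps.append({"type": "status_within_strain",
                          "pair": (f"M_{strain}_{s1}", f"M_{strain}_{s2}")})
    for status in MALE_STATUSES:
        for g1, g2 in combinations(STRAINS, 2):
            comps.append({"type": "strain_within_status",
                          "pair": (f"M_{g1}_{status}", f"M_{g2}_{status}")})
    return comps


def selectivity_comparison_table(matrix: ResponseMatrix,
                                 comparisons: list[dict] | None = None,
                                 alpha: float = 0.05) -> pd.DataFrame:
    """Pairwise-selectivity state comparison table with a Bonferroni threshold.

    Columns: comparison type, the two stimuli, per-state mean |PI| and unit
    counts, the Kruskal-Wallis p, the family-wise threshold (alpha over the
    number of comparisons), and the corrected significance flag.
    """
    comparisons = comparisons if comparisons is not None else default_state_comparisons()
    threshold = alpha / len(comparisons)
    rows = []
    for comp in comparisons:
        res = pairwise_selectivity_compare(matrix, comp["pair"])
        res["comparison"] = comp.get("type", "custom")
        res["bonferroni_threshold"] = threshold
        res["significant_corrected"] = bool(res["p_value"] < threshold)
        res["significant_uncorrected"] = bool(res["p_value"] < alpha)
        rows.append(res)
    cols = ["comparison", "stim_a", "stim_b", "selectivity_non_estrus", "n_non_estrus",
            "selectivity_estrus", "n_estrus", "p_value", "bonferroni_threshold",
            "significant_corrected", "significant_uncorrected"]
    return pd.DataFrame(rows)[cols]
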