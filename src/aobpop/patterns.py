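"""Receptive-field response patterns and their shuffle-null statistics.

A pattern is a conjunction of conditions, each demanding that every stimulus
in a *preferred* set elicit a strictly stronger response than every stimulus
in a *compared* set. Basic patterns (e.g. FEMALE, DOM, MALE_C57) use a single
condition whose compared set is the rest of the panel; strain- and
state-adjusted patterns impose one condition per strain (or per virility
status), restricted to same-strain (same-status) male stimuli. The
complementary pattern (~X) reverses every inequality, which is equivalent to
swapping the preferred and compared sets of each condition.

Over/under-representation of a pattern in a response matrix is assessed
against a column-shuffle null: each iteration independently permutes the
order of values within every stimulus column, preserving per-stimulus
marginals while destroying within-unit correlations, and the pattern count
is recomputed. The p-value is the fraction of shuffles whose count is at
least the observed count (observed-inclusive tail by default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .stimuli import PANEL_TOKENS, STRAINS, MALE_STATUSES, female_tokens, male_tokens

logger = logging.getLogger(__name__)

#: Reusable column blocks for the shuffle-null group min/max cache: strain
#: triplets, virility-status triplets, and the female pair cover every set
#: the default registry's conditions use.
_BASE_BLOCKS: tuple[frozenset, ...] = tuple(
    [frozenset(male_tokens(strain=s)) for s in STRAINS]
    + [frozenset(male_tokens(status=st)) for st in MALE_STATUSES]
    + [frozenset(female_tokens())]
)

__all__ = [
    "PatternCondition",
    "PatternDefinition",
    "PatternRegistry",
    "PatternResult",
    "default_registry",
    "load_registry",
    "classify_unit",
    "count_patterns",
    "shuffle_null",
]


@dataclass(frozen=True)
class PatternCondition:
    """One strict-inequality block: min(preferred) > max(compared)."""

    preferred: tuple[str, ...]
    compared: tuple[str, ...]

    def __post_init__(self) -> None:
        if set(self.preferred) & set(self.compared):
            raise ValueError("preferred and compared stimulus sets must be disjoint")
        if not self.preferred or not self.compared:
            raise ValueError("preferred and compared sets must be nonempty")

    def swapped(self) -> "PatternCondition":
        return PatternCondition(self.compared, self.preferred)


@dataclass(frozen=True)
class PatternDefinition:
    """A named pattern: a conjunction of :class:`PatternCondition` blocks."""

    id: str
    conditions: tuple[PatternCondition, ...]
    group: str = "basic"            # "basic" or "adjusted"
    complement_of: str | None = None

    @property
    def is_complement(self) -> bool:
        return self.complement_of is not None

    def complement(self) -> "PatternDefinition":
        """The pattern with every inequality reversed."""
        return PatternDefinition(
            id=f"~{self.id}",
            conditions=tuple(c.swapped() for c in self.conditions),
            group=self.group,
            complement_of=self.id,
        )


@dataclass
class PatternRegistry:
    """Ordered collection of pattern definitions, grouped for Bonferroni families."""

    patterns: list[PatternDefinition] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [p.id for p in self.patterns]
        if len(ids) != len(set(ids)):
            raise ValueError("pattern ids must be unique")

    def __iter__(self):
        return iter(self.patterns)

    def __len__(self) -> int:
        return len(self.patterns)

    def __getitem__(self, pattern_id: str) -> PatternDefinition:
        for p in self.patterns:
            if p.id == pattern_id:
                return p
        raise KeyError(pattern_id)

    def ids(self) -> list[str]:
        return [p.id for p in self.patterns]

    def group(self, name: str) -> list[PatternDefinition]:
        return [p for p in self.patterns if p.group == name]

    def family_size(self, name: str) -> int:
        """Number of patterns (including complements) in a Bonferroni family."""
        return len(self.group(name))


def _expand_entry(entry: dict, group: str) -> PatternDefinition:
    pid = str(entry["id"])
    if "conditions" in entry:
        conds = tuple(
            PatternCondition(tuple(c["preferred"]), tuple(c["compared"]))
            for c in entry["conditions"]
        )
    else:
        preferred = tuple(entry["preferred"])
        compared = tuple(t for t in PANEL_TOKENS if t not in preferred)
        conds = (PatternCondition(preferred, compared),)
    return PatternDefinition(id=pid, conditions=conds, group=group)


def load_registry(source: str | Path | dict) -> PatternRegistry:
    """Load a pattern registry from a YAML file (or a pre-parsed mapping).

    Schema::

        auto_complement: true
        groups:
          basic:
            - {id: FEMALE, preferred: [F_ICR_EST, F_ICR_NON_EST]}
          adjusted:
            - id: DOM_STRAIN
              conditions:
                - {preferred: [M_ICR_DOM], compared: [M_ICR_NAIVE, M_ICR_CAST]}
                ...

    ``preferred`` without ``compared`` means "versus the rest of the panel".
    With ``auto_complement`` every pattern's complement (~id) is appended.
    """
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            spec = yaml.safe_load(fh)
    else:
        spec = source
    auto_comp = bool(spec.get("auto_complement", True))
    patterns: list[PatternDefinition] = []
    for group, entries in spec.get("groups", {}).items():
        base = [_expand_entry(e, group) for e in entries]
        patterns.extend(base)
        if auto_comp:
            patterns.extend(p.complement() for p in base)
    return PatternRegistry(patterns)


def default_registry() -> PatternRegistry:
    """The shipped default registry: 8 basic + 8 complements, 6 adjusted + 6 complements."""
    ref = resources.files("aobpop").joinpath("data/default_registry.yaml")
    with resources.as_file(ref) as path:
        return load_registry(path)


# ---------------------------------------------------------------------------
# Classification


def _column_index(stimuli: Sequence[str]) -> dict[str, int]:
    return {tok: i for i, tok in enumerate(stimuli)}


def fulfills(values: np.ndarray, pattern: PatternDefinition,
             stimuli: Sequence[str] = PANEL_TOKENS) -> np.ndarray:
    """Vectorised pattern test on the last axis of ``values``.

    ``values`` has shape (..., n_stimuli); returns a boolean array of shape
    ``values.shape[:-1]``. Strict inequalities: ties fail.
    """
    values = np.asarray(values, dtype=float)
    if values.shape[-1] != len(stimuli):
        raise ValueError("response vector length does not match the stimulus panel")
    if np.isnan(values).any():
        raise ValueError("response values contain NaN; every stimulus must have a magnitude")
    idx = _column_index(stimuli)
    ok = np.ones(values.shape[:-1], dtype=bool)
    for cond in pattern.conditions:
        pref = values[..., [idx[t] for t in cond.preferred]].min(axis=-1)
        comp = values[..., [idx[t] for t in cond.compared]].max(axis=-1)
        ok &= pref > comp
    return ok


def classify_unit(magnitudes: Sequence[float] | pd.Series, pattern: PatternDefinition,
                  stimuli: Sequence[str] | None = None) -> bool:
    """Does one unit's raw 11-stimulus magnitude vector fulfil ``pattern``?

    Magnitudes are the raw baseline-subtracted rates; significance plays no
    role. A missing (NaN) value is an error.
    """
    if isinstance(magnitudes, pd.Series) and stimuli is None:
        stimuli = list(magnitudes.index)
    stimuli = list(stimuli) if stimuli is not None else list(PANEL_TOKENS)
    vec = np.asarray(magnitudes, dtype=float)
    return bool(fulfills(vec, pattern, stimuli))


def count_patterns(magnitudes: pd.DataFrame | np.ndarray,
                   registry: PatternRegistry,
                   stimuli: Sequence[str] | None = None) -> pd.Series:
    """Number of units fulfilling each registry pattern.

    Rows are units, columns stimuli. A unit may fulfil several patterns, so
    the counts may sum to more than the number of units.
    """
    if isinstance(magnitudes, pd.DataFrame):
        stimuli = list(magnitudes.columns)
        values = magnitudes.to_numpy(dtype=float)
    else:
        values = np.asarray(magnitudes, dtype=float)
        stimuli = list(stimuli) if stimuli is not None else list(PANEL_TOKENS)
    counts = {p.id: int(fulfills(values, p, stimuli).sum()) for p in registry}
    return pd.Series(counts, name="observed")


def membership(magnitudes: pd.DataFrame, registry: PatternRegistry) -> pd.DataFrame:
    """Boolean units x patterns fulfilment table."""
    stimuli = list(magnitudes.columns)
    values = magnitudes.to_numpy(dtype=float)
    data = {p.id: fulfills(values, p, stimuli) for p in registry}
    return pd.DataFrame(data, index=magnitudes.index)


# ---------------------------------------------------------------------------
# Shuffle null


@dataclass
class PatternResult:
    """Observed count, shuffle-null distribution summary, and p-value for one pattern."""

    pattern_id: str
    observed_count: int
    null_counts: np.ndarray
    p_value: float
    n_shuffles: int

    @property
    def null_mean(self) -> float:
        return float(self.null_counts.mean())

    @property
    def overrepresented(self) -> bool:
        return self.p_value < 0.05


def shuffle_null(magnitudes: pd.DataFrame | np.ndarray,
                 registry: PatternRegistry,
                 n_shuffles: int = 100_000,
                 seed: int | np.random.Generator | None = None,
                 stimuli: Sequence[str] | None = None,
                 tail: str = "ge",
                 batch_size: int = 100) -> dict[str, PatternResult]:
    """Column-shuffle null distribution and p-value for every registry pattern.

    Each iteration permutes every stimulus column independently and recounts
    all patterns. ``tail='ge'`` (default) counts shuffles with count >=
    observed; ``'gt'`` uses a strict tail.
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    if tail not in ("ge", "gt"):
        raise ValueError("tail must be 'ge' or 'gt'")
    if isinstance(magnitudes, pd.DataFrame):
        stimuli = list(magnitudes.columns)
        values = magnitudes.to_numpy(dtype=float)
    else:
        values = np.asarray(magnitudes, dtype=float)
        stimuli = list(stimuli) if stimuli is not None else list(PANEL_TOKENS)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_units, n_stim = values.shape
    idx = _column_index(stimuli)

    observed = {p.id: int(fulfills(values, p, stimuli).sum()) for p in registry}
    null = {p.id: np.empty(n_shuffles, dtype=np.int32) for p in registry}

    # stimuli-major layout so each column permutation runs on a contiguous axis
    values_t = np.ascontiguousarray(values.T)  # (n_stim, n_units)

    done = 0
    while done < n_shuffles:
        b = min(batch_size, n_shuffles - done)
        # Independent permutation of every stimulus column in every shuffle:
        # argsort of uniform keys along the unit axis.
        keys = rng.random((b, n_stim, n_units), dtype=np.float32)
        order = np.argsort(keys, axis=2)
        shuffled = np.take_along_axis(
            np.broadcast_to(values_t, (b, n_stim, n_units)), order, axis=2
        )
        # memoized min/max over column groups, shared across patterns;
        # large groups are composed greedily from cached base blocks
        # (strain triplets, status triplets, the female pair)
        mins: dict[frozenset, np.ndarray] = {}
        maxs: dict[frozenset, np.ndarray] = {}

        def reduce_group(tokens: tuple[str, ...], how: str) -> np.ndarray:
            key = frozenset(tokens)
            cache = mins if how == "min" else maxs
            if key in cache:
                return cache[key]
            op = np.minimum if how == "min" else np.maximum
            remaining = set(tokens)
            parts: list[np.ndarray] = []
            if key not in _BASE_BLOCKS:
                for block in _BASE_BLOCKS:
                    if block <= remaining:
                        parts.append(reduce_group(tuple(block), how))
                        remaining -= block
            parts.extend(shuffled[:, idx[t], :] for t in sorted(remaining))
            out = parts[0].copy()
            for c in parts[1:]:
                out = op(out, c, out=out)
            cache[key] = out
            return out

        for p in registry:
            ok = np.ones((b, n_units), dtype=bool)
            for cond in p.conditions:
                ok &= (reduce_group(cond.preferred, "min")
                       > reduce_group(cond.compared, "max"))
            null[p.id][done:done + b] = ok.sum(axis=1)
        done += b

    results: dict[str, PatternResult] = {}
    for p in registry:
        nc = null[p.id]
        if tail == "ge":
            pval = float((nc >= observed[p.id]).mean())
        else:
            pval = float((nc > observed[p.id]).mean())
        results[p.id] = PatternResult(
            pattern_id=p.id, observed_count=observed[p.id],
            null_counts=nc, p_value=pval, n_shuffles=n_shuffles,
        )
    return results


def results_table(results: dict[str, PatternResult], registry: PatternRegistry,
                  alpha: float = 0.05) -> pd.DataFrame:
    """Tidy table of shuffle-null results (pattern, group, observed, null mean, p, flag)."""
    rows = []
    for p in registry:
        r = results[p.id]
        rows.append({
            "pattern": p.id,
            "group": p.group,
            "observed": r.observed_count,
            "null_mean": r.null_mean,
            "p_value": r.p_value,
            "overrepresented": r.p_value < alpha,
        })
    return pd.DataFrame(rows)
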