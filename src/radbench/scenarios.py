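"""Benchmark scenario construction.

Twelve scenarios = {600, 300, 100} samples x {balanced, unbalanced}
outcome x {high, low} signal. Cohorts keep a fixed 2:1 ratio between the
FBP and IR reconstruction strata; outcome prevalence is 50% (balanced) or
30% (unbalanced) *exactly*, not in expectation. Three designated control
features carry the class signal: an additive shift of the positive class
expressed in units of the feature's (pre-shift) cohort standard
deviation. Subsampling to smaller sizes is nested by default and
preserves the training/validation split membership.

All count apportionment uses the largest-remainder method, with strata
filled in order and the last stratum absorbing remainders so that both
the stratum and the class margins are met exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from ._seeds import child_seed
from .reference import STRATA, ReferenceStructure
from .simulate import rescale_to_range, simulate_features

__all__ = [
    "SIGNAL_SHIFTS",
    "SIZES",
    "ScenarioSpec",
    "SimulatedCohort",
    "SplitIndices",
    "table1_counts",
    "assign_outcome",
    "inject_signal",
    "build_full_scenario",
    "subsample",
    "split_train_validation",
    "build_scenario_suite",
]

SIZES = (600, 300, 100)
STRATUM_SHARES = {"FBP": 2.0 / 3.0, "IR": 1.0 / 3.0}
POSITIVE_SHARE = {"balanced": 0.5, "unbalanced": 0.3}

#: class-separation shifts for the three control features, in units of the
#: pre-shift cohort standard deviation. High signal makes all three
#: controls strongly class-associated; low signal only the larger shifts.
SIGNAL_SHIFTS = {"high": (2.0, 2.0, 2.0), "low": (1.2, 0.8, 0.5)}


@dataclass(frozen=True)
class ScenarioSpec:
    """One cell of the size x balancing x signal design."""

    size: int
    balancing: str  # "balanced" | "unbalanced"
    signal: str  # "high" | "low"
    control_features: tuple
    shifts: tuple | None = None

    def __post_init__(self):
        if self.balancing not in POSITIVE_SHARE:
            raise ValueError(f"unknown balancing {self.balancing!r}")
        if self.signal not in SIGNAL_SHIFTS:
            raise ValueError(f"unknown signal level {self.signal!r}")
        if len(set(self.control_features)) != 3:
            raise ValueError("need three distinct control features")
        if self.shifts is None:
            object.__setattr__(self, "shifts", SIGNAL_SHIFTS[self.signal])
        if any(s < 0 for s in self.shifts):
            raise ValueError("shifts must be >= 0")


@dataclass
class SimulatedCohort:
    """Feature matrix + outcome + stratum labels for one scenario."""

    features: pd.DataFrame
    outcome: pd.Series
    stratum: pd.Series
    spec: ScenarioSpec

    @property
    def n(self) -> int:
        return len(self.features)

    def counts(self) -> dict:
        """(stratum, class) -> count."""
        out = {}
        for s in STRATA:
            for y in (0, 1):
                out[(s, y)] = int(((self.stratum == s) & (self.outcome == y)).sum())
        return out


@dataclass(frozen=True)
class SplitIndices:
    """Disjoint training / validation index sets covering the cohort."""

    train: pd.Index
    validation: pd.Index


def largest_remainder(total: int, shares) -> list[int]:
    """Apportion ``total`` into integer counts proportional to ``shares``.

    Ties in the fractional remainders favour earlier entries, which makes
    the apportionment fully deterministic.
    """
    shares = np.asarray(shares, dtype=float)
    quota = total * shares / shares.sum()
    base = np.floor(quota).astype(int)
    rem = quota - base
    short = total - int(base.sum())
    # stable sort descending by remainder; ties keep original order
    order = np.argsort(-rem, kind="stable")
    for k in order[:short]:
        base[k] += 1
    return base.tolist()


def table1_counts(size: int, balancing: str) -> dict:
    """Per-(stratum, class) sample counts of the scenario design.

    Class totals and stratum totals are apportioned by largest remainder;
    strata are then filled in order with classes apportioned within each
    stratum (ties to class 0), the last stratum taking the remainders, so
    both margins are met exactly.
    """
    p_pos = POSITIVE_SHARE[balancing]
    n_neg, n_pos = largest_remainder(size, [1.0 - p_pos, p_pos])
    stratum_totals = dict(
        zip(STRATA, largest_remainder(size, [STRATUM_SHARES[s] for s in STRATA]))
    )
    remaining = {0: n_neg, 1: n_pos}
    counts = {}
    for k, s in enumerate(STRATA):
        if k == len(STRATA) - 1:
            cell = {0: remaining[0], 1: remaining[1]}
        else:
            neg, pos = largest_remainder(stratum_totals[s], [1.0 - p_pos, p_pos])
            cell = {0: min(neg, remaining[0]), 1: min(pos, remaining[1])}
            # cap against the class margins, give back any shortfall
            shortfall = stratum_totals[s] - cell[0] - cell[1]
            if shortfall:
                for y in (0, 1):
                    take = min(shortfall, remaining[y] - cell[y])
                    cell[y] += take
                    shortfall -= take
        for y in (0, 1):
            counts[(s, y)] = cell[y]
            remaining[y] -= cell[y]
    return counts


def assign_outcome(n: int, balancing: str, seed: int) -> np.ndarray:
    """Binary outcome vector with the exact design prevalence."""
    if n < 2:
        raise ValueError("need n >= 2 to realize both classes")
    n_neg, n_pos = largest_remainder(n, [1.0 - POSITIVE_SHARE[balancing], POSITIVE_SHARE[balancing]])
    if n_pos == 0 or n_neg == 0:
        raise ValueError(f"n={n} too small to realize both classes")
    y = np.zeros(n, dtype=int)
    rng = np.random.default_rng(seed)
    y[rng.choice(n, size=n_pos, replace=False)] = 1
    return y


def inject_signal(cohort: SimulatedCohort, spec: ScenarioSpec | None = None) -> SimulatedCohort:
    """Shift the control features additively in the positive class.

    The shift for control k is ``shifts[k]`` times the feature's standard
    deviation computed over the whole cohort *before* shifting (equal to
    the pooled within-class SD, as both classes share the same pre-shift
    distribution). Negative-class rows are untouched bit for bit.
    """
    spec = spec or cohort.spec
    X = cohort.features.copy()
    for fid in spec.control_features:
        if fid not in X.columns:
            raise KeyError(f"unknown control feature {fid!r}")
    pos = cohort.outcome.to_numpy() == 1
    for fid, shift in zip(spec.control_features, spec.shifts):
        sd = float(X[fid].std(ddof=1))
        X.loc[pos, fid] = X.loc[pos, fid] + shift * sd
    return SimulatedCohort(features=X, outcome=cohort.outcome.copy(), stratum=cohort.stratum.copy(), spec=spec)


def build_full_scenario(
    ref: ReferenceStructure, spec: ScenarioSpec, seed: int, n_total: int = 600
) -> SimulatedCohort:
    """Simulate the full-size cohort (default 600) for one scenario.

    Features are simulated separately per stratum from that stratum's
    moments and correlation target, rescaled to their physical ranges,
    assigned outcomes within stratum to hit the design counts exactly,
    stacked, and finally signal-injected.
    """
    counts = table1_counts(n_total, spec.balancing)
    frames, ys, strata = [], [], []
    for stratum in STRATA:
        n_s = counts[(stratum, 0)] + counts[(stratum, 1)]
        sim = simulate_features(
            ref.moments[stratum],
            ref.correlations[stratum],
            n_s,
            child_seed(seed, "simulate", stratum, spec.balancing, spec.signal),
        )
        for s_spec in ref.moments[stratum]:
            sim[s_spec.feature_id] = rescale_to_range(
                sim[s_spec.feature_id].to_numpy(), s_spec.range_min, s_spec.range_max
            )
        y = np.zeros(n_s, dtype=int)
        rng = np.random.default_rng(child_seed(seed, "outcome", stratum, spec.balancing, spec.signal))
        y[rng.choice(n_s, size=counts[(stratum, 1)], replace=False)] = 1
        frames.append(sim)
        ys.append(y)
        strata.extend([stratum] * n_s)
    X = pd.concat(frames, ignore_index=True)
    cohort = SimulatedCohort(
        features=X,
        outcome=pd.Series(np.concatenate(ys), name="outcome"),
        stratum=pd.Series(strata, name="stratum"),
        spec=replace(spec, size=n_total),
    )
    return inject_signal(cohort)


def split_train_validation(cohort: SimulatedCohort, seed: int) -> SplitIndices:
    """Stratified 2/3 - 1/3 split by (class x stratum).

    Per-cell training counts apportion round(2n/3) across the cells by
    largest remainder, so totals are conserved exactly.
    """
    if cohort.n < 3:
        raise ValueError("need at least 3 samples to split 2/3 - 1/3")
    cells = [(s, y) for s in STRATA for y in (0, 1)]
    cell_counts = cohort.counts()
    if any(cell_counts[c] == 0 for c in cells):
        raise ValueError(f"empty (stratum x class) cell: {cell_counts}")
    n_train = largest_remainder(cohort.n, [2.0, 1.0])[0]
    quota = np.array([cell_counts[c] for c in cells], dtype=float) * 2.0 / 3.0
    base = np.floor(quota).astype(int)
    rem = quota - base
    extra = n_train - int(base.sum())
    for k in np.argsort(-rem, kind="stable")[:extra]:
        base[k] += 1
    rng = np.random.default_rng(seed)
    train_idx, val_idx = [], []
    for (s, y), n_cell_train in zip(cells, base):
        members = cohort.features.index[
            (cohort.stratum == s).to_numpy() & (cohort.outcome == y).to_numpy()
        ].to_numpy()
        chosen = rng.choice(members, size=n_cell_train, replace=False)
        train_idx.extend(chosen.tolist())
        val_idx.extend(np.setdiff1d(members, chosen).tolist())
    return SplitIndices(train=pd.Index(sorted(train_idx)), validation=pd.Index(sorted(val_idx)))


def _cell_split_counts(size: int, balancing: str) -> dict:
    """(stratum, class) -> (train, validation) counts at a given size."""
    counts = table1_counts(size, balancing)
    cells = [(s, y) for s in STRATA for y in (0, 1)]
    n_train = largest_remainder(size, [2.0, 1.0])[0]
    quota = np.array([counts[c] for c in cells], dtype=float) * 2.0 / 3.0
    base = np.floor(quota).astype(int)
    extra = n_train - int(base.sum())
    rem = quota - base
    for k in np.argsort(-rem, kind="stable")[:extra]:
        base[k] += 1
    return {c: (int(b), counts[c] - int(b)) for c, b in zip(cells, base)}


def subsample(
    cohort: SimulatedCohort,
    size: int,
    seed: int,
    split: SplitIndices | None = None,
):
    """Simple random subsample preserving the design counts.

    Without ``split``: returns a cohort whose (stratum x class) counts
    match :func:`table1_counts` for the new size. With ``split``: samples
    within each (stratum x class x train/validation) cell so the split
    membership is preserved (nested subsampling), and returns
    ``(cohort, SplitIndices)`` for the new size.
    """
    if size > cohort.n:
        raise ValueError(f"cannot subsample {size} from {cohort.n}")
    rng = np.random.default_rng(seed)
    stratum_arr = cohort.stratum
    outcome_arr = cohort.outcome
    chosen: list[int] = []
    if split is None:
        counts = table1_counts(size, cohort.spec.balancing)
        for (s, y), n_cell in counts.items():
            members = cohort.features.index[
                (stratum_arr == s).to_numpy() & (outcome_arr == y).to_numpy()
            ].to_numpy()
            if n_cell > members.size:
                raise ValueError(f"cell {(s, y)} has only {members.size} members, need {n_cell}")
            chosen.extend(rng.choice(members, size=n_cell, replace=False).tolist())
        idx = pd.Index(sorted(chosen))
        return SimulatedCohort(
            features=cohort.features.loc[idx],
            outcome=outcome_arr.loc[idx],
            stratum=stratum_arr.loc[idx],
            spec=replace(cohort.spec, size=size),
        )
    cell_splits = _cell_split_counts(size, cohort.spec.balancing)
    new_train: list[int] = []
    new_val: list[int] = []
    for (s, y), (n_tr, n_va) in cell_splits.items():
        mask = (stratum_arr == s).to_numpy() & (outcome_arr == y).to_numpy()
        members = cohort.features.index[mask]
        for pool, n_cell, sink in (
            (members.intersection(split.train), n_tr, new_train),
            (members.intersection(split.validation), n_va, new_val),
        ):
            if n_cell > len(pool):
                raise ValueError(
                    f"cell {(s, y)}: need {n_cell} but only {len(pool)} available in split"
                )
            sink.extend(rng.choice(pool.to_numpy(), size=n_cell, replace=False).tolist())
    idx = pd.Index(sorted(new_train + new_val))
    sub = SimulatedCohort(
        features=cohort.features.loc[idx],
        outcome=outcome_arr.loc[idx],
        stratum=stratum_arr.loc[idx],
        spec=replace(cohort.spec, size=size),
    )
    return sub, SplitIndices(train=pd.Index(sorted(new_train)), validation=pd.Index(sorted(new_val)))


def build_scenario_suite(
    ref: ReferenceStructure,
    balancing: str,
    signal: str,
    seed: int,
    sizes: tuple = SIZES,
    nested: bool = True,
) -> dict:
    """Build the size ladder for one (balancing, signal) combination.

    Returns ``{size: (cohort, split)}``. With ``nested=True`` (default)
    smaller cohorts are subsets of larger ones and split membership is
    preserved down the ladder.
    """
    sizes = tuple(sorted(sizes, reverse=True))
    spec = ScenarioSpec(
        size=sizes[0], balancing=balancing, signal=signal, control_features=ref.controls
    )
    full = build_full_scenario(ref, spec, seed, n_total=sizes[0])
    split = split_train_validation(full, child_seed(seed, "split", balancing, signal))
    out = {sizes[0]: (full, split)}
    current, cur_split = full, split
    for size in sizes[1:]:
        sub_seed = child_seed(seed, "subsample", balancing, signal, size)
        if nested:
            current, cur_split = subsample(current, size, sub_seed, split=cur_split)
            out[size] = (current, cur_split)
        else:
            sub = subsample(full, size, sub_seed)
            sub_split = split_train_validation(sub, child_seed(seed, "resplit", size))
            out[size] = (sub, sub_split)
    return out
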