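"""Target statistical description of radiomic-like feature tables.

The benchmark needs, per reconstruction stratum (FBP and IR), a target
correlation matrix and per-feature moments (skewness, excess kurtosis)
plus physical ranges. Real NSCLC summaries are not public, so
:func:`build_reference_stats` produces a parametric stand-in: features
grouped into correlated blocks (high within-block, low between-block
correlation), roughly one third approximately normal and the rest
right-skewed and heavy-tailed, with block-dependent magnitudes. Real
summaries, where available, load through :func:`load_reference_stats`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._seeds import child_seed
from .fleishman import fleishman_feasible

__all__ = [
    "STRATA",
    "MomentSpec",
    "CorrelationTarget",
    "ReferenceStructure",
    "build_reference_stats",
    "load_reference_stats",
    "save_reference_stats",
]

STRATA = ("FBP", "IR")

#: conservative interior approximation of the Fleishman feasibility
#: boundary; sampled kurtosis values start this far above it
_BOUNDARY_A, _BOUNDARY_B = -1.2264489, 1.6410373


class ReferenceConfigError(ValueError):
    """Raised when reference-structure parameters cannot be realized."""


@dataclass(frozen=True)
class MomentSpec:
    """Target moments and range for one feature in one stratum."""

    feature_id: str
    stratum: str
    skewness: float
    excess_kurtosis: float
    range_min: float
    range_max: float
    block_id: int

    def __post_init__(self):
        if self.stratum not in STRATA:
            raise ValueError(f"unknown stratum {self.stratum!r}")
        if not self.range_min < self.range_max:
            raise ValueError(
                f"feature {self.feature_id}: range_min must be < range_max"
            )


@dataclass(frozen=True)
class CorrelationTarget:
    """Target feature-feature correlation matrix for one stratum."""

    matrix: pd.DataFrame
    stratum: str

    def __post_init__(self):
        m = self.matrix.to_numpy(dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("correlation matrix must be square")
        if list(self.matrix.index) != list(self.matrix.columns):
            raise ValueError("correlation matrix row/column ids must match")
        if not np.allclose(m, m.T, atol=1e-10):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(m), 1.0, atol=1e-10):
            raise ValueError("correlation matrix must have unit diagonal")
        if np.any(np.abs(m) > 1.0 + 1e-10):
            raise ValueError("correlation entries must lie in [-1, 1]")


@dataclass(frozen=True)
class ReferenceStructure:
    """Moments + correlation targets for both strata, and control ids."""

    moments: dict  # stratum -> list[MomentSpec]
    correlations: dict  # stratum -> CorrelationTarget
    controls: tuple  # three feature ids carrying the outcome signal

    @property
    def feature_ids(self) -> list[str]:
        return [s.feature_id for s in self.moments[STRATA[0]]]


def _block_template(n_features: int, n_blocks: int, within: float, between: float):
    """Deterministic block correlation template and block assignment."""
    blocks = np.array([i * n_blocks // n_features for i in range(n_features)])
    same = blocks[:, None] == blocks[None, :]
    m = np.where(same, within, between).astype(float)
    np.fill_diagonal(m, 1.0)
    return m, blocks


def build_reference_stats(
    n_features: int = 168,
    n_blocks: int = 8,
    normal_fraction: float = 0.32,
    seed: int = 0,
    within: float = 0.7,
    between: float = 0.1,
    skew_range: tuple[float, float] = (0.5, 3.0),
    kurt_margin: tuple[float, float] = (0.3, 6.0),
    max_attempts: int = 100,
) -> ReferenceStructure:
    """Generate the stand-in reference statistics for both strata.

    Roughly ``normal_fraction`` of features are approximately normal
    (skewness 0, excess kurtosis 0); the rest draw skewness uniformly from
    ``skew_range`` and excess kurtosis uniformly above the Fleishman
    feasibility boundary, offset by ``kurt_margin``. The correlation
    template is block structured (``within`` inside, ``between`` across
    blocks) and shared by both strata. Control features are the first
    features of three well-separated blocks.
    """
    if not (n_features >= n_blocks >= 1):
        raise ReferenceConfigError("need n_features >= n_blocks >= 1")
    if not 0.0 <= normal_fraction <= 1.0:
        raise ReferenceConfigError("normal_fraction must be in [0, 1]")

    template, blocks = _block_template(n_features, n_blocks, within, between)
    ids = [f"F{i + 1:03d}" for i in range(n_features)]
    corr_df = pd.DataFrame(template, index=ids, columns=ids)

    # block magnitudes cycle over decades: radiomic ranges vary a lot
    magnitudes = 10.0 ** ((np.arange(n_blocks) % 5) - 1)

    moments: dict[str, list[MomentSpec]] = {}
    for stratum in STRATA:
        rng = np.random.default_rng(child_seed(seed, "reference", stratum))
        is_normal = rng.random(n_features) < normal_fraction
        specs = []
        for i, fid in enumerate(ids):
            if is_normal[i]:
                g1, g2 = 0.0, 0.0
            else:
                for _ in range(max_attempts):
                    g1 = float(rng.uniform(*skew_range))
                    lower = _BOUNDARY_A + _BOUNDARY_B * g1 * g1
                    g2 = float(lower + rng.uniform(*kurt_margin))
                    if fleishman_feasible(g1, g2):
                        break
                else:
                    raise ReferenceConfigError(
                        f"could not draw a feasible (skewness, kurtosis) pair "
                        f"for {fid} after {max_attempts} attempts"
                    )
            mag = float(magnitudes[blocks[i]])
            specs.append(
                MomentSpec(
                    feature_id=fid,
                    stratum=stratum,
                    skewness=g1,
                    excess_kurtosis=g2,
                    range_min=0.0,
                    range_max=100.0 * mag,
                    block_id=int(blocks[i]),
                )
            )
        moments[stratum] = specs

    correlations = {s: CorrelationTarget(corr_df.copy(), s) for s in STRATA}

    # controls in three distinct, well-separated blocks -> low mutual
    # correlation, no redundant signal
    control_blocks = [0, n_blocks // 3, (2 * n_blocks) // 3]
    control_blocks = sorted(set(b % n_blocks for b in control_blocks))
    while len(control_blocks) < min(3, n_blocks):
        control_blocks.append((control_blocks[-1] + 1) % n_blocks)
    controls = []
    for b in control_blocks[:3]:
        idx = int(np.argmax(blocks == b))
        controls.append(ids[idx])
    if n_blocks < 3:  # degenerate: fall back to distinct features
        controls = ids[: min(3, n_features)]

    return ReferenceStructure(moments=moments, correlations=correlations, controls=tuple(controls))


MOMENT_COLUMNS = [
    "feature_id",
    "stratum",
    "skewness",
    "excess_kurtosis",
    "range_min",
    "range_max",
    "block_id",
]


def save_reference_stats(ref: ReferenceStructure, moments_path, correlation_path) -> None:
    """Write moments (long CSV, both strata) and the correlation matrix."""
    rows = [
        {c: getattr(s, c) for c in MOMENT_COLUMNS}
        for stratum in STRATA
        for s in ref.moments[stratum]
    ]
    # %.17g guarantees exact float64 round-trip through text
    pd.DataFrame(rows, columns=MOMENT_COLUMNS).to_csv(
        moments_path, index=False, float_format="%.17g"
    )
    ref.correlations[STRATA[0]].matrix.to_csv(correlation_path, float_format="%.17g")


def load_reference_stats(
    moments_path, correlation_path, controls: tuple[str, str, str] | None = None
) -> ReferenceStructure:
    """Load reference statistics written by :func:`save_reference_stats`.

    Validates moment-spec and correlation-matrix invariants; PSD repair of
    the matrix is deferred to the simulator. ``controls`` defaults to the
    first feature of three distinct blocks.
    """
    mom = pd.read_csv(moments_path, float_precision="round_trip")
    missing = set(MOMENT_COLUMNS) - set(mom.columns)
    if missing:
        raise ValueError(f"moments file missing columns: {sorted(missing)}")
    corr = pd.read_csv(correlation_path, index_col=0, float_precision="round_trip")
    corr.index = corr.index.astype(str)
    corr.columns = corr.columns.astype(str)

    moments: dict[str, list[MomentSpec]] = {}
    for stratum in STRATA:
        sub = mom[mom["stratum"] == stratum]
        if sub.empty:
            raise ValueError(f"moments file has no rows for stratum {stratum!r}")
        if sub["feature_id"].duplicated().any():
            dupes = sub.loc[sub["feature_id"].duplicated(), "feature_id"].tolist()
            raise ValueError(f"duplicated feature_id in stratum {stratum!r}: {dupes}")
        specs = [
            MomentSpec(
                feature_id=str(r.feature_id),
                stratum=stratum,
                skewness=float(r.skewness),
                excess_kurtosis=float(r.excess_kurtosis),
                range_min=float(r.range_min),
                range_max=float(r.range_max),
                block_id=int(r.block_id),
            )
            for r in sub.itertuples()
        ]
        for s in specs:
            if not fleishman_feasible(s.skewness, s.excess_kurtosis):
                raise ValueError(
                    f"feature {s.feature_id} ({stratum}): infeasible "
                    f"(skewness={s.skewness}, excess kurtosis={s.excess_kurtosis})"
                )
        ids = [s.feature_id for s in specs]
        if set(ids) != set(corr.index):
            raise ValueError(
                f"feature ids mismatch between moments ({stratum}) and correlation files"
            )
        moments[stratum] = specs

    ids = [s.feature_id for s in moments[STRATA[0]]]
    corr = corr.loc[ids, ids]
    correlations = {s: CorrelationTarget(corr.copy(), s) for s in STRATA}

    if controls is None:
        block_of = {s.feature_id: s.block_id for s in moments[STRATA[0]]}
        seen: dict[int, str] = {}
        for fid in ids:
            seen.setdefault(block_of[fid], fid)
            if len(seen) == 3:
                break
        controls = tuple(list(seen.values())[:3])
        if len(controls) < 3:
            controls = tuple(ids[:3])
    return ReferenceStructure(moments=moments, correlations=correlations, controls=tuple(controls))
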