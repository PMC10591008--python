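"""Follow-up design enumeration, classification and dataset subsampling.

A *design* is a baseline-anchored ordered subset of acquisition sessions.
With 5 sessions and 3 retained acquisitions the menu is the reference design
``D_R`` (all sessions) plus the six tested designs ``D_012, D_013, D_014,
D_023, D_024, D_034`` — digits give the retained 0-based session indices.
Designs are classified by duration (week of the last retained session) and
interval type: *balanced* when nominal gaps between retained sessions are
equal, otherwise *unbalanced* (short-first or long-first depending on the
first gap).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from itertools import combinations
from typing import Optional, Sequence

from .synthetic import LongitudinalDataset

__all__ = [
    "DesignSpec",
    "DesignError",
    "REFERENCE_NAME",
    "enumerate_designs",
    "classify_design",
    "design_name",
    "parse_design",
    "subsample",
    "default_designs",
]

REFERENCE_NAME = "D_R"

INTERVAL_TYPES = (
    "reference", "balanced", "unbalanced_short_first", "unbalanced_long_first",
)


class DesignError(ValueError):
    """Invalid design or design/dataset mismatch."""


@dataclass(frozen=True)
class DesignSpec:
    """An ordered baseline-anchored subset of session indices.

    ``duration_weeks`` and ``interval_type`` are filled by
    :func:`classify_design`; they are ``None`` on a bare spec.
    """

    name: str
    session_indices: tuple[int, ...]
    duration_weeks: Optional[float] = None
    interval_type: Optional[str] = None

    def __post_init__(self) -> None:
        idx = tuple(int(i) for i in self.session_indices)
        object.__setattr__(self, "session_indices", idx)
        if len(idx) < 2:
            raise DesignError("a design needs at least 2 sessions")
        if idx[0] != 0:
            raise DesignError("baseline (session 0) must always be retained")
        if any(b >= a for b, a in zip(idx, idx[1:])):
            raise DesignError("session_indices must be strictly increasing")

    @property
    def m(self) -> int:
        """Number of retained acquisitions."""
        return len(self.session_indices)

    def to_json(self) -> str:
        return json.dumps({"name": self.name,
                           "session_indices": list(self.session_indices)})

    @classmethod
    def from_json(cls, text: str) -> "DesignSpec":
        d = json.loads(text)
        return cls(name=d["name"], session_indices=tuple(d["session_indices"]))


def design_name(session_indices: Sequence[int], n_sessions: Optional[int] = None) -> str:
    """Canonical name for an index subset: ``D_R`` if it is the full set,
    else ``D_`` followed by the concatenated indices (e.g. ``D_014``)."""
    idx = tuple(session_indices)
    if n_sessions is not None and idx == tuple(range(n_sessions)):
        return REFERENCE_NAME
    return "D_" + "".join(str(i) for i in idx)


def parse_design(name: str, n_sessions: int) -> DesignSpec:
    """Inverse of :func:`design_name` (needs ``n_sessions`` to resolve D_R)."""
    if name == REFERENCE_NAME:
        return DesignSpec(REFERENCE_NAME, tuple(range(n_sessions)))
    if not name.startswith("D_") or not name[2:].isdigit():
        raise DesignError(f"cannot parse design name {name!r}")
    idx = tuple(int(c) for c in name[2:])
    if any(i >= n_sessions for i in idx):
        raise DesignError(f"design {name!r} references a session >= {n_sessions}")
    return DesignSpec(name, idx)


def enumerate_designs(n_sessions: int, k: int) -> list[DesignSpec]:
    """All baseline-anchored k-session designs plus the full reference design.

    Returns the reference first, then the C(n_sessions - 1, k - 1) tested
    designs in lexicographic index order.  For ``n_sessions=5, k=3`` this is
    exactly the seven-design menu used throughout.
    """
    if not 2 <= k <= n_sessions:
        raise DesignError(f"k must be in [2, {n_sessions}], got {k}")
    designs = [DesignSpec(REFERENCE_NAME, tuple(range(n_sessions)))]
    for rest in combinations(range(1, n_sessions), k - 1):
        idx = (0,) + rest
        if len(idx) == n_sessions:
            continue  # identical to the reference
        designs.append(DesignSpec(design_name(idx), idx))
    return designs


def classify_design(d: DesignSpec,
                    session_weeks: Sequence[float]) -> DesignSpec:
    """Fill in ``duration_weeks`` and ``interval_type`` from the nominal
    schedule.

    Classification uses nominal session weeks, not jittered acquisition
    times: balanced/unbalanced is a property of the planned schedule.
    """
    weeks = [float(w) for w in session_weeks]
    if d.session_indices[-1] >= len(weeks):
        raise DesignError(
            f"design {d.name} references session {d.session_indices[-1]} "
            f"but only {len(weeks)} sessions are scheduled"
        )
    duration = weeks[d.session_indices[-1]]
    if d.session_indices == tuple(range(len(weeks))):
        itype = "reference"
    else:
        gaps = [weeks[b] - weeks[a]
                for a, b in zip(d.session_indices, d.session_indices[1:])]
        if all(abs(g - gaps[0]) < 1e-9 for g in gaps):
            itype = "balanced"
        elif gaps[0] < gaps[1]:
            itype = "unbalanced_short_first"
        else:
            itype = "unbalanced_long_first"
    return replace(d, duration_weeks=duration, interval_type=itype)


def default_designs(session_weeks: Sequence[float] = (0, 4, 8, 12, 16),
                    k: int = 3) -> list[DesignSpec]:
    """The packaged design menu, classified: reference + all k-subsets."""
    return [classify_design(d, session_weeks)
            for d in enumerate_designs(len(session_weeks), k)]


def subsample(dataset: LongitudinalDataset, d: DesignSpec) -> LongitudinalDataset:
    """Restrict ``dataset`` to the sessions retained by design ``d``.

    Covariate, clinical and truth tables pass through unchanged (clinical
    change is always anchored at the full study's first and last visits).
    """
    present = set(dataset.session_indices)
    missing = [i for i in d.session_indices if i not in present]
    if missing:
        raise DesignError(
            f"design {d.name} needs session(s) {missing} absent from the dataset"
        )
    records = dataset.records[
        dataset.records["session_index"].isin(d.session_indices)
    ].reset_index(drop=True)
    return LongitudinalDataset(
        records=records,
        covariates=dataset.covariates,
        clinical=dataset.clinical,
        truth=dataset.truth,
    )
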