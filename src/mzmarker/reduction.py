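"""Linear-dependence detection and elimination over feature columns.

Columns (m/z channels) that are linear combinations of earlier columns
are detected by Gauss-Jordan elimination with partial pivoting and a
relative pivot tolerance, grouped with the channels they depend on, and
replaced by a single representative per group — the member with the
maximum median intensity across all vectors (ties broken toward lower
m/z). Eliminated channels remain available through the group map so the
annotation stage can still match their ions.

Grouping convention: every pivot (independent) column keys one group; a
dependent column joins the group of the pivot carrying its largest
absolute coefficient (ties toward lower m/z). Columns with no resolvable
support (all-zero channels) join the first pivot's group. Groups
therefore partition the channel set and the number of groups equals the
numerical column rank at the stated tolerance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
import numpy as np

from .exceptions import ConfigError
from .io import IntensityMatrix


@dataclass
class DependencyReduction:
    """Result of dependency analysis on a fixed channel set.

    All channels are identified by their nominal m/z label. The
    ``coefficients`` map stores, for each eliminated channel, its
    representation over the pivot channels (support-thresholded).
    """

    representatives: tuple[int, ...]
    groups: dict[int, tuple[int, ...]]
    pivots: tuple[int, ...]
    pivot_tolerance: float
    mz_labels: tuple[int, ...]
    n_rows_used: int
    coefficients: dict[int, dict[int, float]] = field(default_factory=dict)

    @property
    def eliminated(self) -> tuple[int, ...]:
        kept = set(self.representatives)
        return tuple(m for m in self.mz_labels if m not in kept)

    def expand_to_group(self, channel: int) -> tuple[int, ...]:
        """All member channels represented by ``channel``.

        ``channel`` must be a representative; querying a non-representative
        raises ``KeyError`` (its representative is found via ``groups``).
        """
        if channel not in self.groups:
            raise KeyError(
                f"mz_{channel} is not a representative channel"
            )
        return self.groups[channel]

    def to_json(self) -> str:
        return json.dumps(
            {
                "representatives": list(self.representatives),
                "groups": {str(k): list(v) for k, v in self.groups.items()},
                "pivots": list(self.pivots),
                "pivot_tolerance": self.pivot_tolerance,
                "mz_labels": list(self.mz_labels),
                "n_rows_used": self.n_rows_used,
                "coefficients": {
                    str(k): {str(p): c for p, c in v.items()}
                    for k, v in self.coefficients.items()
                },
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "DependencyReduction":
        d = json.loads(text)
        return cls(
            representatives=tuple(d["representatives"]),
            groups={int(k): tuple(v) for k, v in d["groups"].items()},
            pivots=tuple(d["pivots"]),
            pivot_tolerance=d["pivot_tolerance"],
            mz_labels=tuple(d["mz_labels"]),
            n_rows_used=d["n_rows_used"],
            coefficients={
                int(k): {int(p): c for p, c in v.items()}
                for k, v in d["coefficients"].items()
            },
        )


def find_dependent_groups(
    matrix: IntensityMatrix, pivot_tolerance: float = 1e-8
) -> DependencyReduction:
    """Detect linearly dependent channels by Gauss-Jordan elimination.

    Columns are processed in ascending m/z order with partial (max
    magnitude) row pivoting. A column whose entries, after elimination
    against all previous pivots, are all below
    ``pivot_tolerance * max|original column|`` is dependent; its reduced
    entries on the pivot rows are its coefficients over the pivot
    columns. The procedure is deterministic given column order and
    tolerance, and group contents are invariant under row permutation
    (the reduced row-echelon form is canonical).
    """
    if pivot_tolerance <= 0:
        raise ConfigError(f"pivot_tolerance must be positive, got {pivot_tolerance}")
    if matrix.n_rows < 1:
        raise ConfigError("matrix must have at least one row")

    work = matrix.values.astype(float).copy()
    n_rows, n_cols = work.shape
    col_max = np.abs(work).max(axis=0)

    pivot_row_of_col: dict[int, int] = {}  # column index -> pivot row
    pivot_cols: list[int] = []
    used_rows = np.zeros(n_rows, dtype=bool)
    dependent: dict[int, np.ndarray] = {}  # column index -> coefficients over pivots

    for j in range(n_cols):
        if len(pivot_cols) < n_rows:
            candidates = np.where(used_rows, 0.0, work[:, j])
            r = int(np.argmax(np.abs(candidates)))
            if np.abs(candidates[r]) > pivot_tolerance * max(col_max[j], 0.0) and col_max[j] > 0:
                used_rows[r] = True
                pivot_row_of_col[j] = r
                pivot_cols.append(j)
                work[r, :] /= work[r, j]
                factors = work[:, j].copy()
                factors[r] = 0.0
                work -= np.outer(factors, work[r, :])
                continue
        coeffs = work[[pivot_row_of_col[p] for p in pivot_cols], j] if pivot_cols else np.array([])
        dependent[j] = coeffs

    if not pivot_cols:
        raise ConfigError("matrix has no nonzero column; nothing to represent")

    mz = matrix.mz
    # assign each dependent column to the group of its dominant pivot
    members_of_pivot: dict[int, list[int]] = {p: [p] for p in pivot_cols}
    coefficients: dict[int, dict[int, float]] = {}
    for j, coeffs in dependent.items():
        if coeffs.size and np.abs(coeffs).max() > 0:
            support_cut = pivot_tolerance * np.abs(coeffs).max()
            support = np.flatnonzero(np.abs(coeffs) > support_cut)
            dominant = pivot_cols[int(support[np.argmax(np.abs(coeffs[support]))])]
            coefficients[int(mz[j])] = {
                int(mz[pivot_cols[k]]): float(coeffs[k]) for k in support
            }
        else:
            dominant = pivot_cols[0]  # zero column: degenerate, park with first pivot
            coefficients[int(mz[j])] = {}
        members_of_pivot[dominant].append(j)

    # representative per group: maximum median intensity, ties -> lower m/z
    medians = np.median(matrix.values, axis=0)
    groups: dict[int, tuple[int, ...]] = {}
    representatives: list[int] = []
    for p, members in members_of_pivot.items():
        best = min(members, key=lambda c: (-medians[c], mz[c]))
        rep = int(mz[best])
        groups[rep] = tuple(int(mz[c]) for c in sorted(members))
        representatives.append(rep)

    return DependencyReduction(
        representatives=tuple(sorted(representatives)),
        groups=groups,
        pivots=tuple(int(mz[p]) for p in pivot_cols),
        pivot_tolerance=pivot_tolerance,
        mz_labels=tuple(int(m) for m in mz),
        n_rows_used=n_rows,
        coefficients=coefficients,
    )


def reduce(matrix: IntensityMatrix, reduction: DependencyReduction) -> IntensityMatrix:
    """Keep only representative channels; row metadata is untouched."""
    if tuple(int(m) for m in matrix.mz) != tuple(reduction.mz_labels):
        raise ConfigError("matrix channel labels do not match the reduction")
    return matrix.select_channels(reduction.representatives)


def expand_to_group(reduction: DependencyReduction, channel: int) -> tuple[int, ...]:
    """Module-level convenience mirror of ``reduction.expand_to_group``."""
    return reduction.expand_to_group(channel)
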