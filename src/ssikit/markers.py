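"""Core marker-matrix container shared by the simulation, QC, kernel and IO layers."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class MarkerMatrix:
    """Lines x markers table of dominant 0/1 calls with line metadata.

    Parameters
    ----------
    X : ndarray of shape (n_lines, n_markers)
        Presence/absence calls; every entry must be 0 or 1, no missing values.
    ids : array-like of str
        Unique line identifiers, one per row.
    cycles : array-like
        Cycle (generation) label per line.
    families : array-like, optional
        Family label per line.
    marker_ids : array-like of str, optional
        Column names; defaults to ``m0001 ...``.
    """

    X: np.ndarray
    ids: np.ndarray
    cycles: np.ndarray
    families: np.ndarray | None = None
    marker_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X)
        if self.X.ndim != 2:
            raise ValueError("marker matrix must be two-dimensional")
        if np.isnan(self.X.astype(float)).any():
            raise ValueError("missing marker calls are not supported (no imputation)")
        bad = ~np.isin(self.X, (0, 1))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"marker values must be 0/1; found {self.X[i, j]!r} at row {i}, column {j}"
            )
        self.X = self.X.astype(np.int8)
        self.ids = np.asarray(self.ids, dtype=object)
        self.cycles = np.asarray(self.cycles, dtype=object)
        if len(self.ids) != self.X.shape[0] or len(self.cycles) != self.X.shape[0]:
            raise ValueError("ids/cycles length must match number of rows")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate line IDs")
        if self.families is not None:
            self.families = np.asarray(self.families, dtype=object)
            if len(self.families) != self.X.shape[0]:
                raise ValueError("families length must match number of rows")
        if self.marker_ids is None:
            width = max(4, len(str(self.X.shape[1])))
            self.marker_ids = np.array(
                [f"m{k + 1:0{width}d}" for k in range(self.X.shape[1])], dtype=object
            )
        else:
            self.marker_ids = np.asarray(self.marker_ids, dtype=object)
            if len(self.marker_ids) != self.X.shape[1]:
                raise ValueError("marker_ids length must match number of columns")

    @property
    def n_lines(self) -> int:
        return self.X.shape[0]

    @property
    def n_markers(self) -> int:
        return self.X.shape[1]

    def presence_freq(self) -> np.ndarray:
        """Per-marker frequency of the presence (1) call."""
        return self.X.mean(axis=0)

    def select_markers(self, keep: np.ndarray) -> "MarkerMatrix":
        """Return a copy restricted to the marker columns in ``keep`` (bool mask or indices)."""
        keep = np.asarray(keep)
        return MarkerMatrix(
            X=self.X[:, keep],
            ids=self.ids.copy(),
            cycles=self.cycles.copy(),
            families=None if self.families is None else self.families.copy(),
            marker_ids=self.marker_ids[keep],
        )

    def index_of(self, line_ids) -> np.ndarray:
        lookup = {lid: k for k, lid in enumerate(self.ids)}
        try:
            return np.array([lookup[i] for i in line_ids], dtype=int)
        except KeyError as exc:
            raise KeyError(f"unknown line ID {exc.args[0]!r}") from None
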