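"""Participant x condition x time-bin cell tables.

Both the tonic and the phasic analyses reduce trials to a complete
subjects x conditions x bins grid of cell means before ANOVA.  Missing
participant x condition cells (a participant who happened to produce no
trial of some condition) are filled with the mean of that condition x
bin over all participants who did -- the grand mean of observed cells
per column is therefore unchanged by imputation.  Imputed cells stay
flagged in ``imputed_mask``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError


@dataclass
class CellTable:
    """Complete-or-holey grid of cell means; NaN marks a missing cell."""

    participants: list[str]
    conditions: list[str]
    values: np.ndarray        # (n_participants, n_conditions, n_bins)
    imputed_mask: np.ndarray  # bool, same shape

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.imputed_mask = np.asarray(self.imputed_mask, dtype=bool)
        if self.values.shape != self.imputed_mask.shape:
            raise ValidationError("values/imputed_mask shape mismatch")
        if self.values.shape[:2] != (len(self.participants),
                                     len(self.conditions)):
            raise ValidationError("grid shape inconsistent with labels")

    @property
    def n_bins(self) -> int:
        return self.values.shape[2]

    @property
    def complete(self) -> bool:
        return bool(np.isfinite(self.values).all())

    def to_frame(self) -> pd.DataFrame:
        """Tidy long format: one row per participant x condition x bin."""
        rows = []
        for i, p in enumerate(self.participants):
            for j, c in enumerate(self.conditions):
                for b in range(self.n_bins):
                    rows.append((p, c, b + 1, self.values[i, j, b],
                                 bool(self.imputed_mask[i, j, b])))
        return pd.DataFrame(
            rows, columns=["participant_id", "condition", "bin", "value",
                           "imputed"]
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CellTable":
        participants = sorted(df["participant_id"].astype(str).unique())
        conditions = list(pd.unique(df["condition"]))
        bins = sorted(df["bin"].unique())
        values = np.full((len(participants), len(conditions), len(bins)),
                         np.nan)
        imputed = np.zeros_like(values, dtype=bool)
        pidx = {p: i for i, p in enumerate(participants)}
        cidx = {c: j for j, c in enumerate(conditions)}
        bidx = {b: k for k, b in enumerate(bins)}
        for r in df.itertuples(index=False):
            values[pidx[str(r.participant_id)], cidx[r.condition],
                   bidx[r.bin]] = r.value
            if hasattr(r, "imputed"):
                imputed[pidx[str(r.participant_id)], cidx[r.condition],
                        bidx[r.bin]] = bool(r.imputed)
        return cls(participants, [str(c) for c in conditions], values, imputed)


def build_cell_table(
    records: Sequence[tuple[str, str, np.ndarray]],
    conditions: Sequence[str],
) -> CellTable:
    """Average per-trial bin vectors into a participant x condition grid.

    Parameters
    ----------
    records
        ``(participant_id, condition, bins)`` triples, one per trial.
    conditions
        Fixed condition ordering for the grid columns.
    """
    if not records:
        raise ValidationError("no trials to tabulate")
    n_bins = len(records[0][2])
    participants = sorted({r[0] for r in records})
    pidx = {p: i for i, p in enumerate(participants)}
    cidx = {c: j for j, c in enumerate(conditions)}
    sums = np.zeros((len(participants), len(conditions), n_bins))
    counts = np.zeros((len(participants), len(conditions)))
    for pid, cond, bins in records:
        bins = np.asarray(bins, dtype=float)
        if len(bins) != n_bins:
            raise ValidationError("inconsistent bin count across trials")
        if cond not in cidx:
            raise ValidationError(f"unknown condition {cond!r}")
        sums[pidx[pid], cidx[cond]] += bins
        counts[pidx[pid], cidx[cond]] += 1
    with np.errstate(invalid="ignore"):
        values = sums / counts[:, :, None]
    return CellTable(
        participants=list(participants),
        conditions=list(conditions),
        values=values,
        imputed_mask=np.zeros_like(values, dtype=bool),
    )


def impute_condition_means(table: CellTable) -> CellTable:
    """Fill missing participant x condition cells with condition means.

    Each missing cell takes the mean over all non-missing participants
    for that condition x bin.  A condition with zero observations in any
    bin cannot be imputed.
    """
    values = table.values.copy()
    imputed = table.imputed_mask.copy()
    missing = ~np.isfinite(values)
    if not missing.any():
        return CellTable(list(table.participants), list(table.conditions),
                         values, imputed)
    for j, cond in enumerate(table.conditions):
        col = values[:, j, :]                       # participants x bins
        col_missing = ~np.isfinite(col)
        if col_missing.all(axis=0).any():
            raise ValidationError(
                f"condition {cond!r} has no observations to impute from"
            )
        means = np.nanmean(col, axis=0)
        col[col_missing] = np.broadcast_to(means, col.shape)[col_missing]
        imputed[:, j, :] |= col_missing
    return CellTable(list(table.participants), list(table.conditions),
                     values, imputed)
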