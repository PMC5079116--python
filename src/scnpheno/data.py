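"""Core data containers for the single-cell qPCR pipeline.

Raw measurements are cycle-threshold (Ct) values: the qPCR cycle at which a
gene's fluorescence crosses the detection threshold, so *lower* Ct means more
transcript.  Non-detects (reactions that never crossed the threshold) are kept
as an explicit boolean mask alongside a placeholder Ct at the detection limit,
which leaves both the "treat as missing" and the "floor-impute" policies
available downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from ._utils import check_unique

TREATMENTS = ("DD", "LP")  # dark-adapted vs light-pulsed


@dataclass
class CtMatrix:
    """Raw qPCR cycle-threshold values, genes x cells.

    Attributes
    ----------
    values : DataFrame
        Ct cycles, index = gene labels, columns = cell labels.
    nondetect : DataFrame of bool
        True where the reaction did not amplify; same shape as ``values``.
    treatment : Series
        Per-cell label, "DD" (constant darkness) or "LP" (light-pulsed).
    housekeeping : list of str
        Genes used as the normalization reference.
    coordinates : DataFrame, optional
        Per-cell spatial grid indices with columns ``ml`` (mediolateral, 1-7),
        ``vd`` (ventrodorsal, 1-7) and ``section`` (rostrocaudal index).
    """

    values: pd.DataFrame
    nondetect: pd.DataFrame
    treatment: pd.Series
    housekeeping: list = field(default_factory=list)
    coordinates: Optional[pd.DataFrame] = None
    detection_limit_ct: float = 40.0

    def __post_init__(self):
        check_unique(self.values.index, "gene")
        check_unique(self.values.columns, "cell")
        if self.nondetect.shape != self.values.shape:
            raise ValueError("nondetect mask shape must match values")
        self.nondetect = self.nondetect.astype(bool)
        self.nondetect.index = self.values.index
        self.nondetect.columns = self.values.columns
        missing = self.values.columns.difference(self.treatment.index)
        if len(missing):
            raise ValueError(f"cells without treatment label: {list(missing)}")
        self.treatment = self.treatment.reindex(self.values.columns)
        bad = set(self.treatment.unique()) - set(TREATMENTS)
        if bad:
            raise ValueError(f"unknown treatment labels: {sorted(bad)}")
        unknown_hk = [g for g in self.housekeeping if g not in self.values.index]
        if unknown_hk:
            raise ValueError(f"housekeeping genes not in matrix: {unknown_hk}")
        if self.coordinates is not None:
            self.coordinates = self.coordinates.reindex(self.values.columns)
            for axis in ("ml", "vd"):
                col = self.coordinates[axis].dropna()
                if ((col < 1) | (col > 7)).any():
                    raise ValueError(f"{axis} grid indices must lie in 1..7")

    @property
    def gene_ids(self) -> list:
        return list(self.values.index)

    @property
    def cell_ids(self) -> list:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def masked_values(self) -> pd.DataFrame:
        """Ct values with non-detects replaced by NaN."""
        return self.values.mask(self.nondetect)

    def select_cells(self, cells) -> "CtMatrix":
        cells = list(cells)
        return CtMatrix(
            values=self.values[cells].copy(),
            nondetect=self.nondetect[cells].copy(),
            treatment=self.treatment.loc[cells].copy(),
            housekeeping=list(self.housekeeping),
            coordinates=None if self.coordinates is None else self.coordinates.loc[cells].copy(),
            detection_limit_ct=self.detection_limit_ct,
        )

    def select_genes(self, genes) -> "CtMatrix":
        genes = list(genes)
        return CtMatrix(
            values=self.values.loc[genes].copy(),
            nondetect=self.nondetect.loc[genes].copy(),
            treatment=self.treatment.copy(),
            housekeeping=[g for g in self.housekeeping if g in genes],
            coordinates=None if self.coordinates is None else self.coordinates.copy(),
            detection_limit_ct=self.detection_limit_ct,
        )


STAGES = ("minus_dCt", "minus_ddCt", "modified_z")


@dataclass
class ExpressionMatrix:
    """Normalized expression, genes x cells, at one stage of the -ddCt pipeline.

    Stages: ``minus_dCt`` (housekeeping-referenced, higher = more expressed),
    ``minus_ddCt`` (per-gene median-centered across all retained cells) and
    ``modified_z`` (-ddCt divided by the per-gene population SD).
    """

    values: pd.DataFrame
    stage: str
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.stage not in STAGES:
            raise ValueError(f"stage must be one of {STAGES}, got {self.stage!r}")

    @property
    def gene_ids(self) -> list:
        return list(self.values.index)

    @property
    def cell_ids(self) -> list:
        return list(self.values.columns)


@dataclass
class QcReport:
    """Cell/gene exclusions with reason codes; counts must reconcile exactly."""

    excluded_cells: pd.Series  # cell -> reason code
    excluded_genes: pd.Series  # gene -> reason code
    retained_cells: int = 0
    retained_genes: int = 0
    retained_by_treatment: dict = field(default_factory=dict)

    CELL_REASONS = ("failed_reaction", "loading", "signal")
    GENE_REASONS = ("signal", "contamination")

    @property
    def n_excluded_cells(self) -> int:
        return len(self.excluded_cells)

    @property
    def n_excluded_genes(self) -> int:
        return len(self.excluded_genes)

    def summary(self) -> pd.DataFrame:
        rows = [
            ("cells retained", self.retained_cells),
            ("cells excluded", self.n_excluded_cells),
            ("genes retained", self.retained_genes),
            ("genes excluded", self.n_excluded_genes),
        ]
        rows += [(f"cells retained ({t})", n) for t, n in sorted(self.retained_by_treatment.items())]
        return pd.DataFrame(rows, columns=["quantity", "count"])


@dataclass
class GroupPartition:
    """Assignment of cells to phenotype groups.

    Groups are integer ids 1..K ordered by decreasing size; the residual group
    (weakly connected cells pooled outside the detected communities) carries
    the largest id when present.
    """

    assignment: pd.Series  # cell -> int group id
    modularity: float = float("nan")
    residual_group: Optional[int] = None
    provenance: dict = field(default_factory=dict)

    def group_ids(self) -> list:
        return sorted(self.assignment.unique().tolist())

    def members(self, group_id) -> list:
        return self.assignment.index[self.assignment == group_id].tolist()

    def sizes(self) -> pd.Series:
        return self.assignment.value_counts().sort_index()

    @property
    def n_groups(self) -> int:
        return self.assignment.nunique()

    def labels_for(self, cells) -> np.ndarray:
        return self.assignment.loc[list(cells)].to_numpy()
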