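"""Relative qPCR quantification by the 2^-ddCt method.

Target threshold cycles are normalized to the arithmetic mean of the
reference-gene Cts (equivalent to the geometric mean of their linear
quantities), replicates are averaged on the Ct scale within group, and the
fold change of a case group over a control (calibrator) group is
2^-(dCt_case - dCt_control).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .models import ValidationError


@dataclass(frozen=True)
class QpcrAssay:
    sample_id: str
    group: str
    target_ct: float
    reference_cts: tuple[float, ...]
    replicate: int = 1

    def __post_init__(self):
        for ct in (self.target_ct, *self.reference_cts):
            if not 0.0 < ct < 45.0:
                raise ValidationError(f"{self.sample_id}: Ct {ct} outside (0, 45)")
        if not self.reference_cts:
            raise ValidationError(f"{self.sample_id}: at least one reference Ct required")

    @property
    def delta_ct(self) -> float:
        return self.target_ct - float(np.mean(self.reference_cts))


def ddct_fold_change(assays: list[QpcrAssay], case_group: str, control_group: str) -> float:
    """Fold change of the case group over the control (calibrator) group."""

    def group_dct(group: str) -> float:
        dcts = [a.delta_ct for a in assays if a.group == group]
        if not dcts:
            raise ValidationError(f"no assays in group {group!r}")
        return float(np.mean(dcts))

    ddct = group_dct(case_group) - group_dct(control_group)
    return float(2.0 ** (-ddct))


def read_assay_table(path) -> list[QpcrAssay]:
    """Read assays from a TSV with columns sample_id, group, target_ct,
    reference Ct columns (ref_ct_1, ref_ct_2, ...) and optional replicate."""
    df = pd.read_csv(path, sep="\t")
    ref_cols = [c for c in df.columns if c.startswith("ref_ct")]
    if not ref_cols:
        raise ValidationError("assay table needs at least one ref_ct column")
    assays = []
    for _, row in df.iterrows():
        assays.append(
            QpcrAssay(
                sample_id=str(row["sample_id"]),
                group=str(row["group"]),
                target_ct=float(row["target_ct"]),
                reference_cts=tuple(float(row[c]) for c in ref_cols if pd.notna(row[c])),
                replicate=int(row.get("replicate", 1)),
            )
        )
    return assays
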