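"""Relative qPCR expression by the 2^-ddCt method.

Each Ct record pairs a target gene (an ataxin or a DNA-repair gene) with the
normalizer gene (PPIA) in one tissue of one individual.  Delta-Ct corrects
for cDNA input (``ct_target - ct_reference``); delta-delta-Ct then expresses
a tissue relative to a baseline tissue of the *same individual* — here the
cerebellum — and the fold change is ``2 ** -ddCt``.  Technical replicate Cts
are averaged on the Ct scale before any differencing, the field convention.

Amplification-efficiency correction is out of scope; the method assumes
perfect doubling per cycle for both target and reference.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from cagmosaic.errors import BaselineMissingError, PairingError

logger = logging.getLogger(__name__)

BASELINE_TISSUE = "cerebellum"


@dataclass(frozen=True)
class CtRecord:
    """Cycle thresholds for one target/reference pair in one tissue."""

    individual_id: str
    tissue: str
    gene_of_interest: str
    ct_target: float
    ct_reference: float

    def __post_init__(self):
        for name in ("ct_target", "ct_reference"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be finite and positive, got {v}")

    @property
    def delta_ct(self) -> float:
        return self.ct_target - self.ct_reference


def average_replicates(records: Iterable[CtRecord]) -> CtRecord:
    """Collapse technical replicates by arithmetic mean on the Ct scale."""
    records = list(records)
    first = records[0]
    for r in records[1:]:
        if (r.individual_id, r.tissue, r.gene_of_interest) != (
            first.individual_id,
            first.tissue,
            first.gene_of_interest,
        ):
            raise PairingError("replicates must share individual, tissue and gene")
    return CtRecord(
        individual_id=first.individual_id,
        tissue=first.tissue,
        gene_of_interest=first.gene_of_interest,
        ct_target=float(np.mean([r.ct_target for r in records])),
        ct_reference=float(np.mean([r.ct_reference for r in records])),
    )


def fold_change_ddct(sample: CtRecord, baseline: CtRecord) -> float:
    """Relative expression of ``sample`` versus ``baseline``: ``2 ** -ddCt``.

    ``baseline`` must be the same individual's cerebellum record for the
    same target gene; a sample identical to its baseline returns exactly 1.
    """
    if (sample.individual_id, sample.gene_of_interest) != (
        baseline.individual_id,
        baseline.gene_of_interest,
    ):
        raise PairingError(
            f"sample ({sample.individual_id}, {sample.gene_of_interest}) and "
            f"baseline ({baseline.individual_id}, {baseline.gene_of_interest}) "
            f"must share individual and target gene"
        )
    if baseline.tissue != BASELINE_TISSUE:
        raise BaselineMissingError(
            f"baseline must be the {BASELINE_TISSUE}, got {baseline.tissue!r}"
        )
    ddct = sample.delta_ct - baseline.delta_ct
    return float(2.0 ** (-ddct))


def fold_change_table(ct_table: pd.DataFrame) -> pd.DataFrame:
    """Fold changes for a long Ct table, normalized per individual.

    Expects columns ``individual_id, tissue, gene_of_interest, ct_target,
    ct_reference``; technical replicates (duplicate keys) are averaged.
    Each individual x gene is normalized to that individual's cerebellum.
    """
    keys = ["individual_id", "tissue", "gene_of_interest"]
    df = ct_table.groupby(keys, as_index=False)[["ct_target", "ct_reference"]].mean()
    df["delta_ct"] = df["ct_target"] - df["ct_reference"]
    rows = []
    for (ind, gene), sub in df.groupby(["individual_id", "gene_of_interest"]):
        base = sub[sub["tissue"] == BASELINE_TISSUE]
        if base.empty:
            raise BaselineMissingError(
                f"individual {ind!r}, gene {gene!r}: no {BASELINE_TISSUE} baseline"
            )
        base_dct = float(base["delta_ct"].iloc[0])
        for _, row in sub.iterrows():
            rows.append(
                {
                    "individual_id": ind,
                    "gene_of_interest": gene,
                    "tissue": row["tissue"],
                    "fold_change": 2.0 ** (-(row["delta_ct"] - base_dct)),
                }
            )
    return pd.DataFrame(rows)


def scale_for_heatmap(matrix: pd.DataFrame) -> pd.DataFrame:
    """Row-standardize a genes x samples fold-change matrix.

    Each row is scaled to zero mean and unit sample variance, the scaling
    conventionally applied before plotting expression heatmaps.  Constant
    rows cannot be scaled and are set to all zeros with a warning.
    """
    out = matrix.astype(float).copy()
    for idx, row in out.iterrows():
        sd = row.std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            logger.warning("row %r is constant; scaled values set to 0", idx)
            out.loc[idx] = 0.0
        else:
            out.loc[idx] = (row - row.mean()) / sd
    return out
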