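"""Quality-control summaries of spike-in behaviour.

Methylation specificity — the fraction of recovered spike-in fragments
that are methylated — measures immunoprecipitation selectivity.  The
spike-in read fraction checks that the controls consume only a small
share of the sequencing budget.  Alternative-fragment consistency
compares the read counts of same-property 320 bp fragments with
different sequences: similar counts indicate the response depends on
the designed biophysical properties, not on the particular sequence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)


@dataclass
class QCReport:
    methylation_specificity: float | None
    unmethylated_fraction: float | None
    spikein_read_fraction: float | None
    per_fragment_counts: pd.DataFrame
    alternative_ranges: pd.DataFrame

    def as_dict(self) -> dict:
        return {
            "methylation_specificity": self.methylation_specificity,
            "unmethylated_fraction": self.unmethylated_fraction,
            "spikein_read_fraction": self.spikein_read_fraction,
            "alternative_ranges": self.alternative_ranges.to_dict("records"),
        }


def methylation_specificity(table: pd.DataFrame) -> float | None:
    """Total methylated count / total spike-in count (deduplicated
    fragments).  None with a warning when no spike-in fragments were
    recovered."""
    total = table["count"].sum()
    if total == 0:
        log.warning("no spike-in fragments recovered; specificity undefined")
        return None
    meth = table.loc[
        table["methylation_status"] == "methylated", "count"
    ].sum()
    return float(meth) / float(total)


def spikein_read_fraction(
    spikein_total: int, grand_total: int
) -> float | None:
    """Share of all deduplicated fragments mapping to spike-in contigs."""
    if grand_total < spikein_total:
        raise ValueError("grand total smaller than spike-in total")
    if grand_total == 0:
        log.warning("no fragments at all; spike-in fraction undefined")
        return None
    return spikein_total / grand_total


def alternative_consistency(
    tables: list[pd.DataFrame],
) -> pd.DataFrame:
    """Count-consistency ranges for property combinations that have two
    alternative sequences (the 320 bp alternates).

    ``tables`` holds one SpikeInCountTable per replicate.  Methylated
    fragments only (unmethylated counts are dominated by non-specific
    binding).  Per (length, gc, cpg_fraction): the within-alternative
    range is [min, max] over the individual replicate counts of both
    alternatives; the between-alternatives range is the absolute
    difference of the two alternatives' replicate means.
    """
    if isinstance(tables, pd.DataFrame):
        tables = [tables]
    long = pd.concat(
        [t.assign(replicate=i) for i, t in enumerate(tables)],
        ignore_index=True,
    )
    long = long[long["methylation_status"] == "methylated"]
    rows = []
    combos = (
        long[["length_bp", "gc_content", "cpg_fraction"]]
        .drop_duplicates()
        .itertuples(index=False)
    )
    for length, gc, cpg in combos:
        sub = long[
            (long["length_bp"] == length)
            & (long["gc_content"] == gc)
            & (long["cpg_fraction"] == cpg)
        ]
        alts = sorted(sub["alternative_index"].unique())
        if len(alts) < 2:
            continue
        if len(alts) > 2:
            log.warning(
                "combination (%s, %s, %s) has %d alternates; using first two",
                length, gc, cpg, len(alts),
            )
        a1 = sub.loc[sub["alternative_index"] == alts[0], "count"]
        a2 = sub.loc[sub["alternative_index"] == alts[1], "count"]
        allc = pd.concat([a1, a2])
        rows.append(
            {
                "length_bp": length,
                "gc_content": gc,
                "cpg_fraction": cpg,
                "within_min": int(allc.min()),
                "within_max": int(allc.max()),
                "between_means": float(abs(a1.mean() - a2.mean())),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "length_bp", "gc_content", "cpg_fraction",
            "within_min", "within_max", "between_means",
        ],
    )


def qc_report(
    tables,
    grand_total: int | None = None,
) -> QCReport:
    """Assemble the QC report from one or more replicate count tables."""
    if isinstance(tables, pd.DataFrame):
        tables = [tables]
    pooled = pd.concat(tables, ignore_index=True)
    spec = methylation_specificity(pooled)
    spike_total = int(pooled["count"].sum())
    frac = (
        spikein_read_fraction(spike_total, grand_total)
        if grand_total is not None
        else None
    )
    return QCReport(
        methylation_specificity=spec,
        unmethylated_fraction=None if spec is None else 1.0 - spec,
        spikein_read_fraction=frac,
        per_fragment_counts=pooled,
        alternative_ranges=alternative_consistency(tables),
    )
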