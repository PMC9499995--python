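"""Removal of problematic 300 bp genomic windows.

Four criteria, applied in order with per-criterion attribution:
windows overlapping (by >= 1 bp) a simple-repeat interval, windows
overlapping an exclusion blacklist interval, windows whose minimum
mappability score is <= 0.5, and windows whose between-replicate
standard deviation of molar amount is >= 0.05 pmol.  Both thresholds
are inclusive, exactly as stated; the surviving set does not depend on
the order, only the attribution counts do.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_counts import WindowTrack, read_bed


@dataclass
class FilterConfig:
    """Thresholds and exclusion tracks for window filtering.

    mappability_max_excluded: windows with min mappability <= this go.
    sd_threshold: windows with replicate SD (pmol) >= this go.
    """

    mappability_max_excluded: float = 0.5
    sd_threshold: float = 0.05
    repeat_bed: object = None  # path or DataFrame(chrom,start,end)
    blacklist_bed: object = None

    def __post_init__(self):
        if self.mappability_max_excluded < 0 or self.sd_threshold < 0:
            raise ValueError("thresholds must be non-negative")


def replicate_sd(
    tracks, column: str = "amount_pmol", ddof: int = 1
) -> np.ndarray:
    """Per-window sample standard deviation of molar amount across
    replicate tracks (n-1 denominator by default; with two replicates
    this is |a-b|/sqrt(2))."""
    if len(tracks) < 2:
        raise ValueError("replicate SD needs at least 2 replicate tracks")
    keys = tracks[0].key()
    for t in tracks[1:]:
        if not keys.equals(t.key()):
            raise ValueError("replicate tracks have different window sets")
    mat = np.column_stack([t.windows[column].to_numpy() for t in tracks])
    return mat.std(axis=1, ddof=ddof)


def _interval_frame(bed) -> pd.DataFrame:
    if bed is None:
        return pd.DataFrame(columns=["chrom", "start", "end"])
    if isinstance(bed, pd.DataFrame):
        return bed
    return read_bed(bed)


def windows_overlapping(track: WindowTrack, bed: pd.DataFrame) -> np.ndarray:
    """Boolean mask of windows overlapping any interval by >= 1 bp."""
    w = track.windows
    mask = np.zeros(len(w), dtype=bool)
    if len(bed) == 0:
        return mask
    wbp = track.window_bp
    index = {(c, s): i for i, (c, s) in enumerate(zip(w.chrom, w.start))}
    for chrom, s, e in zip(bed["chrom"], bed["start"], bed["end"]):
        if e <= s:
            continue
        first = int(s) // wbp * wbp
        for ws in range(first, int(e), wbp):
            i = index.get((chrom, ws))
            if i is not None:
                mask[i] = True
    return mask


def apply_filters(
    track: WindowTrack,
    sd: np.ndarray | None = None,
    config: FilterConfig | None = None,
) -> tuple[WindowTrack, dict[str, int]]:
    """Drop problematic windows; return the surviving track and a
    removal report {repeats, blacklist, mappability, sd, surviving}.

    Criteria are applied in the order repeats -> blacklist ->
    mappability -> SD, each counting only windows not already removed.
    Mappability uses the track's ``min_mappability`` column when
    present; the SD criterion is skipped when ``sd`` is None.
    """
    config = config or FilterConfig()
    w = track.windows
    n = len(w)
    removed = np.zeros(n, dtype=bool)
    report: dict[str, int] = {}

    for name, bed in (
        ("repeats", config.repeat_bed),
        ("blacklist", config.blacklist_bed),
    ):
        mask = windows_overlapping(track, _interval_frame(bed))
        report[name] = int((mask & ~removed).sum())
        removed |= mask

    if "min_mappability" in w.columns:
        mask = (
            w["min_mappability"].to_numpy()
            <= config.mappability_max_excluded
        )
        report["mappability"] = int((mask & ~removed).sum())
        removed |= mask
    else:
        report["mappability"] = 0

    if sd is not None:
        sd = np.asarray(sd, dtype=float)
        if sd.shape[0] != n:
            raise ValueError("SD vector length does not match window count")
        mask = sd >= config.sd_threshold
        report["sd"] = int((mask & ~removed).sum())
        removed |= mask
    else:
        report["sd"] = 0

    surviving = WindowTrack(
        w.loc[~removed].reset_index(drop=True), track.window_bp
    )
    report["surviving"] = len(surviving)
    return surviving, report
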