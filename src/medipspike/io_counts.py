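"""From aligned paired-end records to deduplicated fragment counts.

Reads are expected aligned against a composite reference: the spike-in
contigs (named as in the catalog) plus genomic chromosomes.  Filtering
follows the preprocessing thresholds used for the spike-in panel: drop a
read pair when either mate has mean base quality < 40 or mapping
quality < 20, collapse PCR duplicates by exact (contig, start, end, UMI)
match, and count fragments per spike-in contig.  Genomic coverage is
summarised on a 300 bp window tiling.

Coordinates are 0-based half-open internally; user-facing tables report
1-start fully-closed positions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .catalog import FragmentCatalog

log = logging.getLogger(__name__)

DEFAULT_MIN_MAPQ = 20
DEFAULT_MIN_PHRED = 40.0
DEFAULT_WINDOW_BP = 300


@dataclass(frozen=True)
class AlignedFragment:
    """A sequenced DNA fragment reconstructed from a read pair."""

    reference_name: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive
    umi: str
    mapq: int = 255
    mean_base_quality: float = 60.0
    is_spikein: bool = False

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError(f"empty fragment {self.start}-{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class DiscardReport:
    """Book-keeping for read pairs removed by the quality filters."""

    mapq: int = 0
    phred: int = 0
    unpaired: int = 0
    unmapped: int = 0
    kept: int = 0

    def as_dict(self) -> dict:
        return dict(mapq=self.mapq, phred=self.phred, unpaired=self.unpaired,
                    unmapped=self.unmapped, kept=self.kept)


def _read_umi(rec) -> str:
    """UMI from the RX tag, or from the read-name suffix after the last
    '_' or ':' (the trimming-with-UMI dialect)."""
    if rec.has_tag("RX"):
        return str(rec.get_tag("RX"))
    name = rec.query_name or ""
    for sep in ("_", ":"):
        if sep in name:
            tail = name.rsplit(sep, 1)[1]
            if tail and set(tail) <= set("ACGTN"):
                return tail
    return ""


def _mean_quality(rec) -> float:
    q = rec.query_qualities
    if q is None or len(q) == 0:
        return 0.0
    return float(np.mean(q))


def filter_alignments(
    records,
    min_mapq: int = DEFAULT_MIN_MAPQ,
    min_phred: float = DEFAULT_MIN_PHRED,
    spikein_ids=None,
) -> tuple[list[AlignedFragment], DiscardReport]:
    """Pair mates, apply quality thresholds, and emit fragments.

    ``records`` is an iterable of pysam.AlignedSegment.  A pair is
    discarded when either mate is unmapped, has mapping quality below
    ``min_mapq``, or mean base quality below ``min_phred``.  Survivors
    become fragments spanning the outer mate coordinates.  Unpaired or
    discordant records are skipped with a warning and counted.
    """
    spikein_ids = set(spikein_ids) if spikein_ids is not None else set()
    report = DiscardReport()
    pending: dict[str, object] = {}
    fragments: list[AlignedFragment] = []

    for rec in records:
        if rec.is_secondary or rec.is_supplementary:
            continue
        if not rec.is_paired:
            report.unpaired += 1
            log.warning("unpaired record %s skipped", rec.query_name)
            continue
        name = rec.query_name
        mate = pending.pop(name, None)
        if mate is None:
            pending[name] = rec
            continue
        pair = (mate, rec)
        if any(r.is_unmapped for r in pair):
            report.unmapped += 1
            continue
        if pair[0].reference_name != pair[1].reference_name:
            report.unpaired += 1
            log.warning("discordant pair %s skipped", name)
            continue
        if any(r.mapping_quality < min_mapq for r in pair):
            report.mapq += 1
            continue
        if any(_mean_quality(r) < min_phred for r in pair):
            report.phred += 1
            continue
        start = min(r.reference_start for r in pair)
        end = max(r.reference_end for r in pair)
        ref = pair[0].reference_name
        fragments.append(
            AlignedFragment(
                reference_name=ref,
                start=start,
                end=end,
                umi=_read_umi(pair[0]),
                mapq=min(r.mapping_quality for r in pair),
                mean_base_quality=min(_mean_quality(r) for r in pair),
                is_spikein=ref in spikein_ids,
            )
        )
        report.kept += 1
    for name in pending:
        report.unpaired += 1
        log.warning("mate of %s never seen; skipped", name)
    return fragments, report


def read_fragments_from_bam(
    path,
    catalog: FragmentCatalog | None = None,
    min_mapq: int = DEFAULT_MIN_MAPQ,
    min_phred: float = DEFAULT_MIN_PHRED,
) -> tuple[list[AlignedFragment], DiscardReport]:
    """Open a SAM/BAM file and run :func:`filter_alignments`."""
    import pysam

    mode = "rb" if str(path).endswith(".bam") else "r"
    ids = set(catalog.ids()) if catalog is not None else set()
    with pysam.AlignmentFile(str(path), mode, check_sq=False) as fh:
        return filter_alignments(fh, min_mapq, min_phred, spikein_ids=ids)


def dedup_umi(
    fragments,
) -> tuple[list[AlignedFragment], int]:
    """Collapse fragments sharing (contig, start, end, UMI) to one.

    Exact-match collapse only — no error-tolerant UMI clustering.
    Returns the deduplicated fragments (first occurrence kept, input
    order preserved) and the number of duplicates removed.
    """
    seen = set()
    out = []
    removed = 0
    for f in fragments:
        key = (f.reference_name, f.start, f.end, f.umi)
        if key in seen:
            removed += 1
            continue
        seen.add(key)
        out.append(f)
    return out, removed


# ---------------------------------------------------------------------------
# spike-in counting


def count_spikeins(
    fragments,
    catalog: FragmentCatalog,
    sample: str = "sample",
) -> pd.DataFrame:
    """Per-spike-in deduplicated fragment counts as a SpikeInCountTable.

    One row per catalog fragment: id, fragment properties, known
    amount_pmol and the deduplicated count (zero when unobserved).
    Fragments aligned to a contig not in the catalog raise.
    """
    ids = catalog.ids()
    idset = set(ids)
    counts = dict.fromkeys(ids, 0)
    for f in fragments:
        if not f.is_spikein and f.reference_name not in idset:
            continue
        if f.reference_name not in idset:
            raise KeyError(
                f"alignment to unknown spike-in contig {f.reference_name!r}"
            )
        counts[f.reference_name] += 1
    df = catalog.to_frame()
    df["sample"] = sample
    df["count"] = [counts[i] for i in df["id"]]
    return df


def make_count_table(
    catalog: FragmentCatalog, counts: dict[str, int], sample: str = "sample"
) -> pd.DataFrame:
    """SpikeInCountTable from a plain id -> count mapping (zero-filled)."""
    df = catalog.to_frame()
    df["sample"] = sample
    df["count"] = [int(counts.get(i, 0)) for i in df["id"]]
    return df


def write_counts_tsv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_counts_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# genomic windows


@dataclass
class WindowTrack:
    """300 bp tiling of the genome with annotations and per-sample amounts.

    ``windows`` holds chrom/start/end (0-based half-open) plus optional
    columns gc_content, cpg_fraction, min_mappability, partial, and any
    number of per-sample amount or count columns.
    """

    windows: pd.DataFrame
    window_bp: int = DEFAULT_WINDOW_BP

    def __len__(self) -> int:
        return len(self.windows)

    def copy(self) -> "WindowTrack":
        return WindowTrack(self.windows.copy(), self.window_bp)

    def key(self) -> pd.Index:
        w = self.windows
        return pd.Index(
            [f"{c}:{s}-{e}" for c, s, e in zip(w.chrom, w.start, w.end)]
        )

    def to_bed_frame(self, columns=()) -> pd.DataFrame:
        cols = ["chrom", "start", "end", *columns]
        return self.windows[cols]

    def write_tsv(self, path, columns=()) -> None:
        self.to_bed_frame(columns).to_csv(
            path, sep="\t", index=False, header=True
        )


def make_windows(chrom_sizes: dict[str, int],
                 window_bp: int = DEFAULT_WINDOW_BP) -> WindowTrack:
    """Half-open tiling [0,w), [w,2w), ... per chromosome; a trailing
    partial window is kept and flagged."""
    rows = []
    for chrom, size in chrom_sizes.items():
        if size <= 0:
            raise ValueError(f"{chrom}: non-positive size {size}")
        for start in range(0, size, window_bp):
            end = min(start + window_bp, size)
            rows.append((chrom, start, end, end - start < window_bp))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "partial"])
    return WindowTrack(df, window_bp)


def annotate_windows(
    track: WindowTrack,
    genome: dict[str, str],
    mappability: pd.DataFrame | None = None,
) -> WindowTrack:
    """Annotate windows with G+C content, CpG fraction and minimum
    overlapping mappability.

    ``genome`` maps chrom -> sequence (a pyfaidx.Fasta also satisfies
    this).  ``mappability`` is a bedGraph frame (chrom, start, end,
    score); windows with no overlapping record get 0.
    """
    w = track.windows.copy()
    gcs, cpgs = [], []
    for chrom, start, end in zip(w.chrom, w.start, w.end):
        if chrom not in genome:
            raise KeyError(f"chromosome {chrom} absent from genome")
        seq = str(genome[chrom][start:end]).upper()
        if len(seq) < end - start:
            raise ValueError(
                f"window {chrom}:{start}-{end} extends past genome end"
            )
        n = len(seq)
        gcs.append((seq.count("G") + seq.count("C")) / n)
        cpgs.append(seq.count("CG") / n)
    w["gc_content"] = gcs
    w["cpg_fraction"] = cpgs
    w["min_mappability"] = overlap_min_score(track, mappability)
    return WindowTrack(w, track.window_bp)


def overlap_min_score(track: WindowTrack,
                      bedgraph: pd.DataFrame | None) -> np.ndarray:
    """Minimum bedGraph score overlapping each window (0 when none)."""
    w = track.windows
    out = np.zeros(len(w))
    if bedgraph is None or len(bedgraph) == 0:
        return out
    filled = np.zeros(len(w), dtype=bool)
    index = {
        (c, s): i
        for i, (c, s) in enumerate(zip(w.chrom, w.start))
    }
    wbp = track.window_bp
    for chrom, s, e, score in zip(
        bedgraph.iloc[:, 0], bedgraph.iloc[:, 1],
        bedgraph.iloc[:, 2], bedgraph.iloc[:, 3],
    ):
        first = int(s) // wbp * wbp
        for ws in range(first, int(e), wbp):
            i = index.get((chrom, ws))
            if i is None:
                continue
            if not filled[i] or score < out[i]:
                out[i] = score
                filled[i] = True
    return out


def read_bed(path) -> pd.DataFrame:
    """Minimal BED reader (chrom, start, end) with line-numbered errors."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("track", "browser", "#")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: fewer than 3 BED columns")
            try:
                rows.append((parts[0], int(parts[1]), int(parts[2])))
            except ValueError as err:
                raise ValueError(f"{path}:{lineno}: {err}") from None
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def read_bedgraph(path) -> pd.DataFrame:
    """bedGraph reader: chrom, start, end, score."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("track", "browser", "#")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(
                    f"{path}:{lineno}: fewer than 4 bedGraph columns"
                )
            try:
                rows.append(
                    (parts[0], int(parts[1]), int(parts[2]), float(parts[3]))
                )
            except ValueError as err:
                raise ValueError(f"{path}:{lineno}: {err}") from None
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "score"])


def read_chrom_sizes(path) -> dict[str, int]:
    sizes = {}
    with open(path) as fh:
        for line in fh:
            if line.strip():
                name, size = line.split()[:2]
                sizes[name] = int(size)
    return sizes
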