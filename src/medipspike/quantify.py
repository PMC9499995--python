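"""Absolute quantification of methylated DNA from spike-in read counts.

The spike-in controls have known molar amounts, so a per-experiment
Gaussian generalized linear model (identity link, i.e. ordinary least
squares) maps fragment covariates to molar amount η in picomoles:

    η = β₀ + β_reads·x_reads + β_len·x_len + β_GC·x_GC
        + β_CpGfraction·∛x_CpGfraction

where x_reads is the deduplicated fragment count, x_len the fragment
length in bp, x_GC the G+C base fraction and x_CpGfraction the CpG
dinucleotides per bp.  The cube root reduces the left skew of the CpG
fraction.  The fitted model is applied to genomic fragments; each
fragment's η is then spread across the 300 bp windows it overlaps in
proportion to the overlap:  η′ = (ℓ/ℓ*)·η with ℓ* = 300 bp.

The model has 5 terms, so at least 6 training spike-ins are required;
rank-deficient designs raise instead of being silently patched.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .catalog import FragmentCatalog
from .io_counts import AlignedFragment, WindowTrack, dedup_umi

N_TERMS = 5
MIN_TRAIN = 6
FEATURE_NAMES = ("beta0", "beta_reads", "beta_len", "beta_gc", "beta_cpg")


class FitError(ValueError):
    """The spike-in design cannot support a well-posed fit."""


@dataclass
class FragmentFeatures:
    """Covariates of one fragment entering the quantification model."""

    x_reads: float
    x_len: float
    x_gc: float
    x_cpg_fraction: float


@dataclass
class QuantModel:
    """Fitted coefficients of the 5-term quantification model."""

    beta0: float
    beta_reads: float
    beta_len: float
    beta_gc: float
    beta_cpg: float
    r_squared: float = float("nan")
    n_train: int = 0

    @property
    def coef(self) -> np.ndarray:
        return np.array(
            [self.beta0, self.beta_reads, self.beta_len,
             self.beta_gc, self.beta_cpg]
        )

    def to_dict(self) -> dict:
        return {
            **dict(zip(FEATURE_NAMES, map(float, self.coef))),
            "r_squared": float(self.r_squared),
            "n_train": int(self.n_train),
        }


def design_matrix(
    x_reads, x_len, x_gc, x_cpg_fraction
) -> np.ndarray:
    """Stack the model covariates, applying the cube-root transform to
    CpG fraction; column order matches ``FEATURE_NAMES``."""
    x_reads = np.asarray(x_reads, dtype=float)
    n = x_reads.shape[0]
    return np.column_stack(
        [
            np.ones(n),
            x_reads,
            np.asarray(x_len, dtype=float),
            np.asarray(x_gc, dtype=float),
            np.cbrt(np.asarray(x_cpg_fraction, dtype=float)),
        ]
    )


def fit_model(
    table: pd.DataFrame,
    use_methylated_only: bool = True,
    weights=None,
) -> QuantModel:
    """Fit the quantification model on a SpikeInCountTable.

    The known molar amount (``amount_pmol``) is the response; the
    deduplicated count is a predictor.  By default only methylated
    spike-ins train the model — unmethylated fragment counts reflect
    non-specific antibody binding, not the amount→count response.
    ``weights`` optionally maps length_bp -> weight for a weighted fit.
    """
    df = table
    if use_methylated_only and "methylation_status" in df.columns:
        df = df[df["methylation_status"] == "methylated"]
    df = df.dropna(subset=["amount_pmol"])
    n = len(df)
    if n < MIN_TRAIN:
        raise FitError(
            f"{n} training spike-ins; the model has {N_TERMS} terms and "
            f"needs at least {MIN_TRAIN}"
        )
    X = design_matrix(
        df["count"], df["length_bp"], df["gc_content"], df["cpg_fraction"]
    )
    y = df["amount_pmol"].to_numpy(dtype=float)
    if weights is not None:
        w = np.sqrt(df["length_bp"].map(weights).to_numpy(dtype=float))
        Xw, yw = X * w[:, None], y * w
    else:
        Xw, yw = X, y
    rank = np.linalg.matrix_rank(Xw)
    if rank < X.shape[1]:
        raise FitError(
            f"rank-deficient design (rank {rank} < {X.shape[1]}); "
            "spike-in covariates are collinear"
        )
    beta, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
    resid = y - X @ beta
    ss_res = float(resid @ resid)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else max(0.0, 1.0 - ss_res / ss_tot)
    return QuantModel(*map(float, beta), r_squared=min(r2, 1.0), n_train=n)


def predict_amount(
    model: QuantModel, features: FragmentFeatures
) -> tuple[float, float]:
    """Predicted molar amount η (pmol) for one fragment.

    Returns (raw, clamped); the identity link can produce negative raw
    predictions, which are floored at zero in the clamped value.
    """
    X = design_matrix(
        [features.x_reads], [features.x_len],
        [features.x_gc], [features.x_cpg_fraction],
    )
    raw = float((X @ model.coef)[0])
    return raw, max(raw, 0.0)


def predict_amounts(model: QuantModel, table: pd.DataFrame) -> np.ndarray:
    """Vectorised raw η over a table with count/length_bp/gc_content/
    cpg_fraction columns."""
    X = design_matrix(
        table["count"], table["length_bp"],
        table["gc_content"], table["cpg_fraction"],
    )
    return X @ model.coef


# ---------------------------------------------------------------------------
# window distribution


@dataclass(frozen=True)
class WindowOverlap:
    """Overlap of one fragment with one window (ℓ bp of ℓ* = window size)."""

    window_index: int
    fragment_index: int
    overlap_bp: int


def fragment_window_overlaps(
    fragments: pd.DataFrame, track: WindowTrack
) -> list[WindowOverlap]:
    """Overlaps between fragments (chrom/start/end frame) and the tiled
    windows, computed arithmetically from the tiling."""
    wbp = track.window_bp
    w = track.windows
    index = {(c, s): i for i, (c, s) in enumerate(zip(w.chrom, w.start))}
    out = []
    for fi, (chrom, start, end) in enumerate(
        zip(fragments["chrom"], fragments["start"], fragments["end"])
    ):
        first = int(start) // wbp * wbp
        for ws in range(first, int(end), wbp):
            wi = index.get((chrom, ws))
            if wi is None:
                continue
            we = int(w.end.iloc[wi])
            ov = min(int(end), we) - max(int(start), ws)
            if ov > 0:
                out.append(WindowOverlap(wi, fi, ov))
    return out


def distribute_to_windows(
    amounts,
    overlaps,
    track: WindowTrack,
    column: str = "amount_pmol",
) -> WindowTrack:
    """Spread per-fragment molar amounts η into windows as η′ = (ℓ/ℓ*)·η.

    ``amounts`` is indexable by fragment index.  A fragment spanning k
    windows contributes to all k; the per-window amount is the sum of
    its overlapping fragments' η′.  Raw (possibly negative) and
    zero-clamped columns are both written.
    """
    amounts = np.asarray(amounts, dtype=float)
    wstar = float(track.window_bp)
    vals = np.zeros(len(track))
    for ov in overlaps:
        if ov.overlap_bp > wstar:
            raise ValueError(
                f"overlap {ov.overlap_bp} bp exceeds window size {wstar}"
            )
        vals[ov.window_index] += (ov.overlap_bp / wstar) * amounts[
            ov.fragment_index
        ]
    out = track.copy()
    out.windows[f"{column}_raw"] = vals
    out.windows[column] = np.maximum(vals, 0.0)
    return out


# ---------------------------------------------------------------------------
# end-to-end per-sample quantification


def group_fragments(fragments) -> pd.DataFrame:
    """Group genomic fragments by identical (chrom, start, end);
    x_reads is the group size."""
    rows = [
        (f.reference_name, f.start, f.end)
        for f in fragments
        if not f.is_spikein
    ]
    if not rows:
        return pd.DataFrame(columns=["chrom", "start", "end", "count"])
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    g = (
        df.groupby(["chrom", "start", "end"], sort=True)
        .size()
        .reset_index(name="count")
    )
    return g


def fragment_features_from_genome(
    grouped: pd.DataFrame, genome: dict[str, str]
) -> pd.DataFrame:
    """Annotate grouped fragments with length, G+C fraction and CpG
    fraction from the reference sequence under the fragment."""
    out = grouped.copy()
    lens, gcs, cpgs = [], [], []
    for chrom, start, end in zip(out["chrom"], out["start"], out["end"]):
        seq = str(genome[chrom][int(start):int(end)]).upper()
        n = len(seq)
        lens.append(n)
        gcs.append((seq.count("G") + seq.count("C")) / n if n else 0.0)
        cpgs.append(seq.count("CG") / n if n else 0.0)
    out["length_bp"] = lens
    out["gc_content"] = gcs
    out["cpg_fraction"] = cpgs
    return out


def quantify_sample(
    fragments,
    catalog: FragmentCatalog,
    genome: dict[str, str],
    track: WindowTrack,
    model: QuantModel | None = None,
    use_methylated_only: bool = True,
    sample: str = "sample",
) -> tuple[WindowTrack, QuantModel]:
    """Quantify one sample end to end.

    Deduplicates the fragments, counts spike-ins, fits the model on the
    sample's own spike-ins (per-experiment coefficients) unless one is
    supplied, predicts η for genomic fragment groups, and distributes
    η′ into the window track.
    """
    from .io_counts import count_spikeins

    deduped, _ = dedup_umi(fragments)
    spike = [f for f in deduped if f.is_spikein]
    if model is None:
        if not spike:
            raise FitError(
                "no spike-in fragments found; check that the alignment "
                "reference contains the catalog contigs"
            )
        table = count_spikeins(spike, catalog, sample=sample)
        model = fit_model(table, use_methylated_only=use_methylated_only)
    grouped = group_fragments(deduped)
    if len(grouped) == 0:
        out = track.copy()
        out.windows["amount_pmol_raw"] = 0.0
        out.windows["amount_pmol"] = 0.0
        return out, model
    feats = fragment_features_from_genome(grouped, genome)
    eta = predict_amounts(model, feats)
    overlaps = fragment_window_overlaps(feats, track)
    out = distribute_to_windows(eta, overlaps, track)
    return out, model


def window_counts(fragments, track: WindowTrack) -> np.ndarray:
    """Deduplicated genomic fragment count per window (a fragment
    spanning several windows adds its overlap fraction to each)."""
    g = group_fragments(fragments)
    counts = np.zeros(len(track))
    if len(g) == 0:
        return counts
    cvals = g["count"].to_numpy()
    for ov in fragment_window_overlaps(g, track):
        counts[ov.window_index] += cvals[ov.fragment_index]
    return counts


def quantify_window_counts(
    model: QuantModel, track: WindowTrack, count_column: str
) -> WindowTrack:
    """Window-level alternative: apply the model with x_len = window
    size and window annotations as covariates."""
    w = track.windows
    X = design_matrix(
        w[count_column],
        np.full(len(w), track.window_bp, dtype=float),
        w["gc_content"],
        w["cpg_fraction"],
    )
    raw = X @ model.coef
    out = track.copy()
    out.windows["amount_pmol_raw"] = raw
    out.windows["amount_pmol"] = np.maximum(raw, 0.0)
    return out


def write_model_json(model: QuantModel, path) -> None:
    import json

    with open(path, "w") as fh:
        json.dump(model.to_dict(), fh, indent=2)


def read_model_json(path) -> QuantModel:
    import json

    with open(path) as fh:
        d = json.load(fh)
    return QuantModel(
        d["beta0"], d["beta_reads"], d["beta_len"], d["beta_gc"],
        d["beta_cpg"], d.get("r_squared", float("nan")), d.get("n_train", 0),
    )
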