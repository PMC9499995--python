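"""Validation of spike-in quantification: held-out accuracy and batch
effects.

Accuracy: for each training-set size from 6 to 25 spike-ins, draw 100
random train/test splits, fit the 5-term model on the training
spike-ins and record the mean absolute error (pmol) between known and
predicted molar amount on the held-out spike-ins.

Batch effects: principal-component analysis of the windows x samples
amount (or count) matrix; per (PC, categorical variable) a one-way
ANOVA of PC scores yields an F statistic, converted to a Cohen's d
effect size, with Holm-Bonferroni adjustment across all tests of one
assessment.  Spike-in normalization should shrink the batch-associated
effect sizes relative to raw counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .quantify import FitError, fit_model, predict_amounts

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# held-out cross-validation (accuracy)


@dataclass
class CVResult:
    """Per-(size, iteration) held-out MAE plus a per-size summary."""

    detail: pd.DataFrame  # columns: size, iteration, mae_pmol, train_ids
    summary: pd.DataFrame  # columns: size, median_mae, max_mae

    @property
    def max_mae(self) -> float:
        return float(self.detail["mae_pmol"].max())


def _split_rng(seed: int, size: int, iteration: int) -> np.random.Generator:
    # independent stream per (seed, size, iteration)
    return np.random.default_rng(np.random.SeedSequence([seed, size, iteration]))


def holdout_cv(
    table: pd.DataFrame,
    sizes=range(6, 26),
    iterations: int = 100,
    seed: int = 0,
    use_methylated_only: bool = True,
) -> CVResult:
    """Held-out spike-in cross-validation of the quantification model.

    Each iteration draws a uniform random training subset without
    replacement, fits the model, predicts the held-out spike-ins and
    records the MAE against their known amounts.  Reproducible given
    ``seed``; iteration i at size s uses an independent substream, so
    any single cell can be recomputed in isolation.
    """
    df = table
    if use_methylated_only and "methylation_status" in df.columns:
        df = df[df["methylation_status"] == "methylated"]
    df = df.dropna(subset=["amount_pmol"]).reset_index(drop=True)
    n = len(df)
    rows = []
    for size in sizes:
        if size <= 5:
            raise FitError(
                f"training size {size} <= 5: the model has 5 terms and "
                "needs more training points than terms"
            )
        if size >= n:
            raise FitError(
                f"training size {size} leaves no held-out spike-ins (n={n})"
            )
        for it in range(1, iterations + 1):
            rng = _split_rng(seed, size, it)
            # rank-deficient draws (e.g. six spike-ins sharing one
            # length) cannot support the 5-term fit; redraw within the
            # iteration's stream so the result stays reproducible
            for _ in range(100):
                train_idx = np.sort(
                    rng.choice(n, size=size, replace=False)
                )
                train = df.iloc[train_idx]
                try:
                    model = fit_model(train, use_methylated_only=False)
                    break
                except FitError:
                    continue
            else:
                raise FitError(
                    f"no full-rank training draw of size {size} found"
                )
            test_mask = np.ones(n, dtype=bool)
            test_mask[train_idx] = False
            test = df.iloc[test_mask]
            pred = predict_amounts(model, test)
            mae = float(
                np.mean(np.abs(test["amount_pmol"].to_numpy() - pred))
            )
            rows.append(
                {
                    "size": size,
                    "iteration": it,
                    "mae_pmol": mae,
                    "train_ids": ",".join(df["id"].iloc[train_idx]),
                }
            )
    detail = pd.DataFrame(rows)
    summary = (
        detail.groupby("size")["mae_pmol"]
        .agg(median_mae="median", max_mae="max")
        .reset_index()
    )
    return CVResult(detail, summary)


# ---------------------------------------------------------------------------
# multiple-testing correction


def holm_adjust(p_values) -> np.ndarray:
    """Holm-Bonferroni step-down adjusted p-values.

    Sort ascending, multiply the i-th (0-based) by (m - i), enforce
    monotone non-decrease along the sorted order, cap at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        p = p.ravel()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj_sorted = p[order] * (m - np.arange(m))
    adj_sorted = np.maximum.accumulate(adj_sorted)
    adj_sorted = np.minimum(adj_sorted, 1.0)
    out = np.empty(m)
    out[order] = adj_sorted
    return out


# ---------------------------------------------------------------------------
# batch-effect assessment


@dataclass
class BatchAssessment:
    """PCA variance fractions plus per-(PC, variable) effect sizes."""

    variance_fraction: np.ndarray  # per PC
    scores: pd.DataFrame  # samples x PCs
    tests: pd.DataFrame  # pc, variable, F, d, p, p_holm

    def effect(self, pc: str, variable: str) -> float:
        t = self.tests
        row = t[(t["pc"] == pc) & (t["variable"] == variable)]
        return float(row["d"].iloc[0])


def f_to_cohens_d(F: float, group_sizes) -> float:
    """Convert a one-way ANOVA F statistic to Cohen's d.

    Two groups: d = sqrt(F (n1+n2) / (n1 n2)).  More groups: eta² =
    F df1 / (F df1 + df2), Cohen's f = sqrt(eta² / (1-eta²)), d = 2f.
    """
    sizes = np.asarray(group_sizes)
    k = len(sizes)
    n = int(sizes.sum())
    if k == 2:
        n1, n2 = sizes
        return float(np.sqrt(F * (n1 + n2) / (n1 * n2)))
    df1, df2 = k - 1, n - k
    eta2 = F * df1 / (F * df1 + df2)
    f = np.sqrt(eta2 / max(1.0 - eta2, np.finfo(float).tiny))
    return float(2 * f)


def pca_scores(matrix: np.ndarray, n_components: int | None = None):
    """PCA of a samples x features matrix: centering only, SVD-based.

    Returns (scores, variance_fraction); variance fractions are over
    the min(samples-1, features) computed components and sum to 1.
    """
    X = np.asarray(matrix, dtype=float)
    keep = X.std(axis=0) > 0
    dropped = int((~keep).sum())
    if dropped:
        log.info("dropping %d zero-variance features before PCA", dropped)
    X = X[:, keep]
    if X.shape[1] == 0:
        raise ValueError("matrix is constant; PCA undefined")
    Xc = X - X.mean(axis=0)
    U, s, _ = np.linalg.svd(Xc, full_matrices=False)
    ncomp = min(X.shape[0] - 1, X.shape[1])
    if n_components is not None:
        ncomp = min(ncomp, n_components)
    scores = U[:, :ncomp] * s[:ncomp]
    var = s[:ncomp] ** 2
    return scores, var / var.sum()


def pca_batch_assessment(
    matrix,
    variables: pd.DataFrame,
    n_components: int | None = None,
) -> BatchAssessment:
    """Assess association of categorical sample variables with the
    principal components of an amounts/counts matrix.

    ``matrix`` is samples x windows (a windows x samples frame is
    transposed when its columns match the variables index).  Per (PC,
    variable): one-way ANOVA of scores by variable level, F converted
    to Cohen's d, and all p-values of the assessment jointly adjusted
    by Holm-Bonferroni.  Variables with fewer than two observed levels
    are skipped with a warning.
    """
    if isinstance(matrix, pd.DataFrame):
        if matrix.shape[0] != len(variables) and matrix.shape[1] == len(
            variables
        ):
            matrix = matrix.T
        matrix = matrix.to_numpy(dtype=float)
    if matrix.shape[0] != len(variables):
        raise ValueError("matrix rows must correspond to samples/labels")
    if matrix.shape[0] < 3:
        raise ValueError("need at least 3 samples")
    scores, var_frac = pca_scores(matrix, n_components)
    pcs = [f"PC{i + 1}" for i in range(scores.shape[1])]
    rows = []
    for i, pc in enumerate(pcs):
        y = scores[:, i]
        for var in variables.columns:
            levels = variables[var].astype(str)
            uniq = levels.unique()
            if len(uniq) < 2:
                log.warning("variable %r has one level; skipped", var)
                continue
            groups = [y[levels.to_numpy() == u] for u in uniq]
            if any(len(g) < 1 for g in groups):
                continue
            F, p = stats.f_oneway(*groups)
            d = f_to_cohens_d(F, [len(g) for g in groups])
            rows.append(
                {"pc": pc, "variable": var, "F": float(F), "d": d,
                 "p": float(p)}
            )
    tests = pd.DataFrame(rows)
    if len(tests):
        tests["p_holm"] = holm_adjust(tests["p"].to_numpy())
    score_df = pd.DataFrame(scores, columns=pcs, index=variables.index)
    return BatchAssessment(var_frac, score_df, tests)


# ---------------------------------------------------------------------------
# end-to-end batch mitigation


def assess_batch_mitigation(
    samples: dict,
    labels: pd.DataFrame,
    catalog,
    track,
    variables=("batch", "filler", "adapter", "sample", "sex"),
):
    """Compare batch effects in raw window counts vs spike-in-normalized
    molar amounts over a set of simulated or real samples.

    ``samples`` maps sample id -> fragment records (or (records, truth)
    pairs).  Each sample is deduplicated, its own spike-ins fit the
    quantification model, and window-level molar amounts are predicted
    from window counts.  Returns (raw_assessment, amount_assessment).
    """
    from .io_counts import count_spikeins, dedup_umi
    from .quantify import quantify_window_counts, window_counts

    raw_rows, amt_rows = [], []
    for sid in labels.index:
        item = samples[sid]
        frags = item[0] if isinstance(item, tuple) else item
        deduped, _ = dedup_umi(frags)
        spike = [f for f in deduped if f.is_spikein]
        model = fit_model(count_spikeins(spike, catalog, sample=sid))
        counts = window_counts(deduped, track)
        t2 = track.copy()
        t2.windows["count"] = counts
        res = quantify_window_counts(model, t2, "count")
        raw_rows.append(counts)
        amt_rows.append(res.windows["amount_pmol_raw"].to_numpy())
    lab = labels[list(variables)]
    raw_assess = pca_batch_assessment(np.vstack(raw_rows), lab)
    amt_assess = pca_batch_assessment(np.vstack(amt_rows), lab)
    return raw_assess, amt_assess


def max_effect(assessment: BatchAssessment, variable: str) -> float:
    """Largest Cohen's d over PCs for one variable."""
    t = assessment.tests
    sub = t[t["variable"] == variable]
    return float(sub["d"].max())


# ---------------------------------------------------------------------------
# replicate correlations


def replicate_correlations(
    reference_track, other_tracks, column: str = "amount_pmol"
) -> pd.Series:
    """Pearson correlation of each track against the reference over
    shared windows (tracks must carry identical window sets)."""
    ref = reference_track.windows[column].to_numpy(dtype=float)
    out = {}
    for i, t in enumerate(other_tracks):
        if not reference_track.key().equals(t.key()):
            raise ValueError("tracks have different window sets")
        x = t.windows[column].to_numpy(dtype=float)
        if ref.std() == 0 or x.std() == 0:
            log.warning("zero-variance track; correlation undefined")
            out[i] = np.nan
            continue
        out[i] = float(np.corrcoef(ref, x)[0, 1])
    return pd.Series(out, name="pearson_r")
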