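"""Ground-truthed synthetic data for the whole pipeline.

The simulator emulates the statistical structure of spike-in read
counts after methylation-dependent immunoprecipitation:

* methylated fragment i has expected deduplicated count
  depth_share * amount_i * w_len(L_i) * exp(a*GC_i + b*cbrt(CpGfrac_i)),
  with length-efficiency weights favouring 160 bp (size selection keeps
  inserts of roughly 80-380 bp) and positive G+C / CpG slopes;
* unmethylated fragments are recovered only by non-specific binding:
  a flat expected count equal to the non-specific rate times the mean
  methylated expectation, independent of fragment properties;
* realized counts are the expectation times multiplicative lognormal
  noise (CV default 0.1), rounded; a Poisson option exists;
* genomic fragments are drawn per window proportional to a latent
  per-window methylated molar amount, PCR duplicates spawn as
  Geometric-count copies sharing UMI and coordinates, and records can
  be written as a SAM/BAM against a generated composite reference;
* a multi-lab batch study shares per-patient truth across labs and
  applies per-lab efficiency multipliers plus filler/adapter labels.

The log-linear bias form is a test harness chosen to be recoverable by
the quantification model in the low-noise limit; it is not a claim
about real immunoprecipitation chemistry.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import catalog as cat
from .catalog import FragmentCatalog, assign_amounts, build_catalog
from .io_counts import AlignedFragment, WindowTrack, make_windows

DEFAULT_LENGTH_WEIGHTS = {80: 0.6, 160: 1.0, 320: 0.4}


@dataclass
class SimConfig:
    """Study conditions for the simulator.

    Defaults mirror the panel's experimental setup: the 52-fragment
    catalog pooled equimolar at 0.01 ng, ~3% of spike-in recovery from
    non-specific binding of unmethylated fragments, multiplicative
    lognormal count noise with CV 0.1, and a small two-chromosome toy
    genome tiled into 300 bp windows.
    """

    seed: int = 0
    catalog: FragmentCatalog | None = None
    pool_mass_ng: float = 0.01
    pool_scheme: str = "per-length-pool"
    depth: int = 100_000  # expected deduplicated spike-in fragments
    length_weights: dict = field(
        default_factory=lambda: dict(DEFAULT_LENGTH_WEIGHTS)
    )
    gc_slope: float = 1.0
    cpg_slope: float = 1.5
    nonspecific_rate: float = 0.03
    noise_cv: float = 0.1
    #: spread of the per-fragment known molar amounts around the nominal
    #: equimolar pool (Qubit-style per-fragment measurement / pipetting
    #: variation); 0 gives an exactly equimolar pool
    amount_cv: float = 0.15
    noise_model: str = "lognormal"  # or "poisson"
    duplication_rate: float = 0.3
    # toy genome
    n_chroms: int = 2
    windows_per_chrom: int = 25
    window_bp: int = 300
    genomic_depth: int = 100_000
    # batch study
    lab_multipliers: tuple = (1.0, 2.0, 0.5)
    fillers: tuple = ("methylated", "methylated", "unmethylated")
    adapters: tuple = ("xGen", "xGen", "custom")

    def resolved_catalog(self) -> FragmentCatalog:
        if self.catalog is not None:
            c = self.catalog
        else:
            c = build_catalog(include_failed=False,
                              pool_mass_ng=self.pool_mass_ng)
        if not c.known_amounts:
            if any(f.sequence is None for f in c):
                c = cat.generate_catalog_sequences(c, seed=self.seed)
            c = assign_amounts(c, self.pool_mass_ng, self.pool_scheme)
            if self.amount_cv > 0:
                # one physical pool: the jitter is a fixed property of
                # the catalog, derived from the seed, shared by every
                # sample/lab of a study
                rng = np.random.default_rng(
                    np.random.SeedSequence([self.seed, 23])
                )
                sigma = np.sqrt(np.log1p(self.amount_cv**2))
                for k in list(c.known_amounts):
                    c.known_amounts[k] *= rng.lognormal(
                        -sigma**2 / 2, sigma
                    )
        return c


@dataclass
class SimTruth:
    """Ground truth persisted alongside every simulated dataset."""

    spikein_expected: pd.DataFrame | None = None  # id, amount, expected
    window_amounts: pd.DataFrame | None = None  # chrom,start,end,true_amount
    labels: pd.DataFrame | None = None


def _noise(rng, n, cv, model):
    if cv == 0 or model == "poisson":
        return np.ones(n)
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(mean=-sigma**2 / 2, sigma=sigma, size=n)


def spikein_expectations(config: SimConfig) -> pd.DataFrame:
    """Expected deduplicated count per catalog fragment under the
    enrichment-bias model (before noise)."""
    c = config.resolved_catalog()
    df = c.to_frame()
    w = df["length_bp"].map(config.length_weights).to_numpy(dtype=float)
    bias = w * np.exp(
        config.gc_slope * df["gc_content"].to_numpy()
        + config.cpg_slope * np.cbrt(df["cpg_fraction"].to_numpy())
    )
    amount = df["amount_pmol"].to_numpy()
    raw = amount * bias
    meth = df["methylation_status"].to_numpy() == "methylated"
    depth_share = config.depth / raw[meth].sum()
    expected = np.where(meth, depth_share * raw, 0.0)
    expected[~meth] = config.nonspecific_rate * expected[meth].mean()
    df["expected_count"] = expected
    return df


def simulate_spikein_counts(
    config: SimConfig,
    rng: np.random.Generator | None = None,
    sample: str = "sample",
) -> tuple[pd.DataFrame, SimTruth]:
    """Simulated SpikeInCountTable plus its generating truth."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    df = spikein_expectations(config)
    mu = df["expected_count"].to_numpy()
    if config.noise_model == "poisson" and config.noise_cv != 0:
        counts = rng.poisson(mu)
    else:
        counts = np.rint(mu * _noise(rng, len(mu), config.noise_cv,
                                     config.noise_model)).astype(int)
    if config.noise_cv == 0 and config.noise_model != "poisson":
        counts = mu  # exact expectations, no rounding
    table = df.drop(columns=["expected_count"]).copy()
    table["sample"] = sample
    table["count"] = counts
    truth = SimTruth(
        spikein_expected=df[
            ["id", "methylation_status", "amount_pmol", "expected_count"]
        ].copy()
    )
    return table, truth


# ---------------------------------------------------------------------------
# genomic sample


def toy_genome(config: SimConfig, rng=None) -> dict[str, str]:
    """Random toy chromosomes with mildly varying G+C and CpG content."""
    rng = rng if rng is not None else np.random.default_rng(
        np.random.SeedSequence([config.seed, 7])
    )
    genome = {}
    for ci in range(config.n_chroms):
        size = config.windows_per_chrom * config.window_bp
        gc = rng.uniform(0.35, 0.6)
        p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
        seq = rng.choice(list("ACGT"), size=size, p=p)
        genome[f"chr{ci + 1}"] = "".join(seq)
    return genome


def latent_window_amounts(
    track: WindowTrack, rng, scale: float = 1e-6
) -> np.ndarray:
    """Latent true methylated molar amount per window.

    A lognormal field whose log is smoothed over adjacent windows
    within each chromosome (methylation is regionally correlated, and
    sequenced fragments span window boundaries), with a handful of
    fully unmethylated (zero) windows.
    """
    w = track.windows
    n = len(track)
    z = rng.normal(0.0, 1.0, size=n)
    smooth = np.empty(n)
    for chrom in w.chrom.unique():
        idx = np.flatnonzero((w.chrom == chrom).to_numpy())
        zc = z[idx]
        pad = np.r_[zc[0], zc, zc[-1]]
        smooth[idx] = (pad[:-2] + 2 * pad[1:-1] + pad[2:]) / 4.0
    amounts = scale * np.exp(1.2 * smooth)
    amounts[rng.random(n) < 0.1] = 0.0
    return amounts


RNG_UMI = np.array(list("ACGT"))


def _umi(rng) -> str:
    # 5 nt per read, two reads per fragment -> 10 nt fragment UMI
    return "".join(rng.choice(RNG_UMI, size=10))


def simulate_genomic_sample(
    config: SimConfig,
    track: WindowTrack | None = None,
    genome: dict[str, str] | None = None,
    window_amounts: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
    lab_multiplier: float = 1.0,
) -> tuple[list[AlignedFragment], SimTruth]:
    """Simulate one sample's deduplicatable fragment records.

    Spike-in fragments are drawn per the count model; genomic fragments
    are drawn per window proportional to the latent methylated amount
    with the same length/composition biases.  PCR duplicates: each
    original spawns D ~ Geometric(mean=duplication_rate) extra copies
    sharing coordinates and UMI, so dedup removes an expected fraction
    r/(1+r) of records.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    c = config.resolved_catalog()
    if genome is None:
        genome = toy_genome(config)
    if track is None:
        track = make_windows(
            {k: len(v) for k, v in genome.items()}, config.window_bp
        )
    if window_amounts is None:
        window_amounts = latent_window_amounts(track, rng)

    fragments: list[AlignedFragment] = []
    # spike-in records
    table, _ = simulate_spikein_counts(
        replace(config, depth=int(config.depth * lab_multiplier)),
        rng=rng,
    )
    for fid, length, n in zip(
        table["id"], table["length_bp"], table["count"]
    ):
        for _ in range(int(n)):
            fragments.append(
                AlignedFragment(fid, 0, int(length), _umi(rng),
                                is_spikein=True)
            )
    # genomic records: expected count per window proportional to amount
    amounts = np.asarray(window_amounts, dtype=float)
    total = amounts.sum()
    w = track.windows
    if total > 0:
        mu = config.genomic_depth * lab_multiplier * amounts / total
        counts = rng.poisson(mu) if config.noise_cv else np.rint(mu).astype(int)
        for (chrom, ws, we), n in zip(
            zip(w.chrom, w.start, w.end), counts
        ):
            chrom_len = len(genome[chrom])
            for _ in range(int(n)):
                # cfDNA-like continuous length distribution (~160 bp
                # mode); a window's molecules are placed within it, so
                # the per-window latent amount is exactly the truth the
                # pipeline should recover
                length = int(np.clip(rng.normal(166, 30), 80, 320))
                lo = int(ws)
                hi = max(int(we) - length, lo + 1)
                start = int(rng.integers(lo, hi))
                end = min(start + length, chrom_len)
                fragments.append(
                    AlignedFragment(chrom, start, end, _umi(rng))
                )
    # PCR duplicates
    r = config.duplication_rate
    if r > 0:
        dup: list[AlignedFragment] = []
        ndup = rng.geometric(1.0 / (1.0 + r), size=len(fragments)) - 1
        for f, k in zip(fragments, ndup):
            dup.extend([f] * (int(k) + 1))
        fragments = dup
        perm = rng.permutation(len(fragments))
        fragments = [fragments[i] for i in perm]

    truth = SimTruth(
        window_amounts=pd.DataFrame(
            {
                "chrom": w.chrom,
                "start": w.start,
                "end": w.end,
                "true_amount": amounts,
            }
        )
    )
    return fragments, truth


def write_sam(
    fragments,
    catalog: FragmentCatalog,
    genome: dict[str, str],
    path,
) -> None:
    """Write simulated fragments as a paired-end SAM against the
    composite reference (spike-in contigs + toy chromosomes)."""
    import pysam

    refs = [(f.id, f.length_bp) for f in catalog]
    refs += [(name, len(seq)) for name, seq in genome.items()]
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": n, "LN": int(l)} for n, l in refs],
    }
    tid = {n: i for i, (n, _) in enumerate(refs)}
    read_len = 50
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for i, f in enumerate(fragments):
            rlen = min(read_len, f.length)
            for mate in (0, 1):
                a = pysam.AlignedSegment()
                a.query_name = f"frag{i}"
                a.reference_id = tid[f.reference_name]
                a.flag = (0x1 | 0x2 | (0x40 if mate == 0 else 0x80)
                          | (0x10 if mate == 1 else 0x20))
                a.reference_start = f.start if mate == 0 else f.end - rlen
                a.mapping_quality = f.mapq
                a.cigarstring = f"{rlen}M"
                a.query_sequence = "A" * rlen
                a.query_qualities = pysam.qualitystring_to_array("I" * rlen)
                a.next_reference_id = a.reference_id
                a.next_reference_start = (
                    f.end - rlen if mate == 0 else f.start
                )
                a.template_length = f.length if mate == 0 else -f.length
                a.set_tag("RX", f.umi)
                out.write(a)


def write_composite_fasta(
    catalog: FragmentCatalog, genome: dict[str, str], path
) -> None:
    with open(path, "w") as fh:
        for f in catalog:
            fh.write(f">{f.id}\n{f.sequence}\n")
        for name, seq in genome.items():
            fh.write(f">{name}\n{seq}\n")


# ---------------------------------------------------------------------------
# multi-lab batch study


def simulate_batch_study(
    config: SimConfig,
    n_labs: int = 3,
    n_patients: int = 5,
) -> tuple[dict[str, tuple[list, SimTruth]], pd.DataFrame,
           dict[str, str], WindowTrack]:
    """Simulate the multi-lab batch experiment.

    Each patient has one latent per-window truth shared by every lab;
    each lab applies its efficiency multiplier to both spike-in and
    genomic depth (so spike-in normalization can cancel it) and gets
    its filler/adapter labels.  Returns (samples, labels, genome,
    track): samples maps sample id -> (fragment records, truth); the
    labels frame has one row per (lab, patient).
    """
    root = np.random.default_rng(config.seed)
    genome = toy_genome(config)
    track = make_windows(
        {k: len(v) for k, v in genome.items()}, config.window_bp
    )
    patient_truth = {
        p: latent_window_amounts(
            track, np.random.default_rng(
                np.random.SeedSequence([config.seed, 11, p])
            )
        )
        for p in range(n_patients)
    }
    sexes = ["F" if root.random() < 0.5 else "M" for _ in range(n_patients)]
    samples = {}
    rows = []
    for lab in range(n_labs):
        mult = config.lab_multipliers[lab % len(config.lab_multipliers)]
        for p in range(n_patients):
            sid = f"lab{lab + 1}_patient{p + 1}"
            rng = np.random.default_rng(
                np.random.SeedSequence([config.seed, 13, lab, p])
            )
            frags, truth = simulate_genomic_sample(
                config,
                track=track,
                genome=genome,
                window_amounts=patient_truth[p],
                rng=rng,
                lab_multiplier=mult,
            )
            truth.labels = None
            samples[sid] = (frags, truth)
            rows.append(
                {
                    "sample_id": sid,
                    "batch": f"lab{lab + 1}",
                    "filler": config.fillers[lab % len(config.fillers)],
                    "adapter": config.adapters[lab % len(config.adapters)],
                    "sample": f"patient{p + 1}",
                    "sex": sexes[p],
                }
            )
    labels = pd.DataFrame(rows).set_index("sample_id")
    return samples, labels, genome, track
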