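"""Design of synthetic spike-in control fragments for cfMeDIP-seq.

The spike-in panel is a full factorial grid over fragment length
(80/160/320 bp), G+C content (35/50/65%) and CpG fraction (1 CpG per
80/40/20 bp), each combination present once methylated and once
unmethylated.  The 320 bp / 65% G+C combinations fold too readily for
synthesis and are replaced by second alternates of three easier
combinations, keeping 18 sequences in the 320 bp class.  Two
160 bp / 35% / 1-in-20 fragments failed synthesis and are flagged.

Sequences are generated from a first-order Markov chain whose transition
probabilities are tuned to the target base composition and CpG rate,
with rejection sampling enforcing the exact G+C base count and exact
CpG dinucleotide count.  Candidate sequences are screened for hairpin
stems (perfect inverted repeats) and for k-mer sharing with a reference
genome.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

LENGTHS = (80, 160, 320)
GC_CONTENTS = (0.35, 0.50, 0.65)
CPG_FRACTIONS = (1 / 80, 1 / 40, 1 / 20)

#: 320 bp / 65% G+C combinations dropped from the final design, and the
#: combinations whose second alternates replace them.
EXCLUDED_320_GC = 0.65
ALTERNATE_320_COMBOS = ((0.35, 1 / 80), (0.50, 1 / 40), (0.50, 1 / 20))

#: (length, gc, cpg_fraction) combinations that failed commercial synthesis.
FAILED_COMBOS = ((160, 0.35, 1 / 20),)

COMPLEMENT = str.maketrans("ACGT", "TGCA")

# Average monoisotopic-free masses (g/mol) of deoxynucleotide monophosphate
# residues in a DNA strand; the 5' end adds back one water / loses HPO3 — the
# conventional -61.96 end correction for a 5'-OH oligo.
_NT_MASS = {"A": 313.21, "C": 289.18, "G": 329.21, "T": 304.20}
_END_CORRECTION = -61.96


class DesignError(ValueError):
    """A fragment specification that cannot be realised as a sequence."""


class GenerationError(RuntimeError):
    """Sequence sampling exhausted its attempt budget for a constraint."""


@dataclass
class FragmentSpec:
    """One designed spike-in fragment and its biophysical properties."""

    id: str
    length_bp: int
    gc_content: float
    cpg_fraction: float
    methylation_status: str  # "methylated" | "unmethylated"
    alternative_index: int = 1
    sequence: str | None = None
    synthesis_ok: bool = True

    @property
    def cpg_count(self) -> int:
        return cpg_count_for(self.length_bp, self.cpg_fraction)

    @property
    def gc_count(self) -> int:
        n = self.length_bp * self.gc_content
        return int(round(n))

    @property
    def molecular_mass(self) -> float | None:
        if self.sequence is None:
            return None
        return molecular_mass_ds(self.sequence)

    def validate_sequence(self) -> None:
        """Re-measure the sequence against the spec; raise on any mismatch."""
        s = self.sequence
        if s is None:
            raise DesignError(f"{self.id}: no sequence attached")
        if len(s) != self.length_bp:
            raise DesignError(f"{self.id}: length {len(s)} != {self.length_bp}")
        gc = sum(s.count(b) for b in "GC")
        if gc != self.gc_count:
            raise DesignError(f"{self.id}: G+C count {gc} != {self.gc_count}")
        if s.count("CG") != self.cpg_count:
            raise DesignError(
                f"{self.id}: CpG count {s.count('CG')} != {self.cpg_count}"
            )


@dataclass
class FragmentCatalog:
    """Ordered collection of spike-in fragments plus pooling metadata."""

    fragments: list[FragmentSpec]
    pool_total_mass_ng: float = 0.01
    #: fragment id -> known molar amount (pmol); filled by assign_amounts
    known_amounts: dict[str, float] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.fragments)

    def __iter__(self):
        return iter(self.fragments)

    def ids(self) -> list[str]:
        return [f.id for f in self.fragments]

    def get(self, frag_id: str) -> FragmentSpec:
        for f in self.fragments:
            if f.id == frag_id:
                return f
        raise KeyError(frag_id)

    def subset(self, ids) -> "FragmentCatalog":
        ids = set(ids)
        return FragmentCatalog(
            [f for f in self.fragments if f.id in ids],
            self.pool_total_mass_ng,
            {k: v for k, v in self.known_amounts.items() if k in ids},
        )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for f in self.fragments:
            rows.append(
                {
                    "id": f.id,
                    "length_bp": f.length_bp,
                    "gc_content": f.gc_content,
                    "cpg_fraction": f.cpg_fraction,
                    "cpg_count": f.cpg_count,
                    "methylation_status": f.methylation_status,
                    "alternative_index": f.alternative_index,
                    "synthesis_ok": f.synthesis_ok,
                    "molecular_mass": f.molecular_mass,
                    "amount_pmol": self.known_amounts.get(f.id, np.nan),
                }
            )
        return pd.DataFrame(rows)


def cpg_count_for(length_bp: int, cpg_fraction: float) -> int:
    """Number of CpG dinucleotides implied by a length and CpG-per-bp rate.

    The panel's CpG fractions were chosen so this product is an integer
    for every fragment length (80 bp fragments carry 1, 2 or 4 CpGs;
    160 bp carry 2, 4 or 8).
    """
    n = length_bp * cpg_fraction
    if abs(n - round(n)) > 1e-9:
        raise DesignError(
            f"length {length_bp} x CpG fraction {cpg_fraction} = {n} "
            "is not an integer number of CpGs"
        )
    return int(round(n))


def _frag_id(length: int, gc: float, cpg: float, status: str, alt: int) -> str:
    dens = int(round(1 / cpg))
    tag = "M" if status == "methylated" else "U"
    return f"spike_{length}bp_gc{int(round(gc * 100))}_cpg1in{dens}_{tag}_alt{alt}"


def build_catalog(
    include_failed: bool = True,
    pool_mass_ng: float = 0.01,
    include_high_gc_320: bool = False,
) -> FragmentCatalog:
    """Build the spike-in fragment grid.

    27 property combinations x 2 methylation statuses = 54 fragments.
    The three 320 bp / 65% G+C combinations are replaced by second
    alternates of (35%, 1/80), (50%, 1/40) and (50%, 1/20), unless
    ``include_high_gc_320`` re-enables them for exploratory use.  With
    ``include_failed=False`` the two fragments that failed synthesis
    (160 bp / 35% / 1-in-20) are dropped, leaving 52.
    """
    if pool_mass_ng <= 0:
        raise ValueError("pool_mass_ng must be positive")
    combos: list[tuple[int, float, float, int]] = []
    for length in LENGTHS:
        for gc in GC_CONTENTS:
            for cpg in CPG_FRACTIONS:
                if (
                    length == 320
                    and gc == EXCLUDED_320_GC
                    and not include_high_gc_320
                ):
                    continue
                combos.append((length, gc, cpg, 1))
    if not include_high_gc_320:
        for gc, cpg in ALTERNATE_320_COMBOS:
            combos.append((320, gc, cpg, 2))

    frags: list[FragmentSpec] = []
    for length, gc, cpg, alt in combos:
        failed = (length, gc, cpg) in FAILED_COMBOS and alt == 1
        for status in ("methylated", "unmethylated"):
            if failed and not include_failed:
                continue
            frags.append(
                FragmentSpec(
                    id=_frag_id(length, gc, cpg, status, alt),
                    length_bp=length,
                    gc_content=gc,
                    cpg_fraction=cpg,
                    methylation_status=status,
                    alternative_index=alt,
                    synthesis_ok=not failed,
                )
            )
    return FragmentCatalog(frags, pool_total_mass_ng=pool_mass_ng)


def n_property_combinations() -> int:
    """Size of the factorial property grid before methylation duplication."""
    return len(LENGTHS) * len(GC_CONTENTS) * len(CPG_FRACTIONS)


# ---------------------------------------------------------------------------
# sequence generation


def _transition_matrix(gc: float, cpg_rate: float) -> np.ndarray:
    """First-order transitions (rows = previous base ACGT) tuned so the
    chain's marginal G+C matches ``gc`` and the expected CpG-per-bp rate
    matches ``cpg_rate``."""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])  # A C G T
    T = np.tile(p, (4, 1))
    # CpG rate == P(prev=C) * P(G | C); pin that entry, rescale the rest of
    # the C row so it still sums to one.
    t_cg = min(cpg_rate / max(p[1], 1e-12), 0.95)
    row = p.copy()
    others = [0, 1, 3]
    row_others = row[others] / row[others].sum() * (1 - t_cg)
    row[others] = row_others
    row[2] = t_cg
    T[1] = row
    return T


def generate_sequence(
    spec: FragmentSpec,
    seed: int,
    max_attempts: int = 100_000,
) -> str:
    """Sample a sequence matching *exactly* the spec's length, G+C base
    count and CpG dinucleotide count.

    Sequences come from a composition-tuned first-order Markov chain;
    draws failing either exact count are rejected.  Deterministic given
    ``seed``.
    """
    L = spec.length_bp
    n_gc = spec.gc_count
    n_cpg = spec.cpg_count
    # feasibility: each CpG consumes one C and one G
    if 2 * n_cpg > n_gc:
        raise GenerationError(
            f"{spec.id}: {n_cpg} CpGs need {2 * n_cpg} G/C bases "
            f"but only {n_gc} are allowed"
        )
    if n_cpg > L - 1 or n_gc > L:
        raise GenerationError(f"{spec.id}: constraints exceed fragment length")

    rng = np.random.default_rng(seed)
    T = _transition_matrix(spec.gc_content, spec.cpg_fraction)
    cum = np.cumsum(T, axis=1)
    start = np.cumsum(
        [(1 - spec.gc_content) / 2, spec.gc_content / 2,
         spec.gc_content / 2, (1 - spec.gc_content) / 2]
    )
    bases = "ACGT"
    for _ in range(max_attempts):
        u = rng.random(L)
        idx = np.empty(L, dtype=np.int64)
        idx[0] = np.searchsorted(start, u[0])
        for i in range(1, L):
            idx[i] = np.searchsorted(cum[idx[i - 1]], u[i])
        gc = int(np.sum((idx == 1) | (idx == 2)))
        if gc != n_gc:
            continue
        seq = "".join(bases[i] for i in idx)
        if seq.count("CG") != n_cpg:
            continue
        return seq
    raise GenerationError(
        f"{spec.id}: no sequence with G+C={n_gc} and CpG={n_cpg} "
        f"found in {max_attempts} attempts"
    )


def generate_catalog_sequences(
    catalog: FragmentCatalog,
    seed: int = 0,
    max_attempts: int = 100_000,
    stem_threshold: int | None = 10,
    reference_kmers: set[str] | None = None,
    k: int = 25,
) -> FragmentCatalog:
    """Attach generated sequences to every fragment in the catalog.

    The methylated and unmethylated fragment of one property combination
    get distinct sequences (two picks per combination, so the two
    statuses can be distinguished after alignment).  Each candidate is
    screened for hairpin stems and, if a reference k-mer set is
    supplied, for genomic matches; failing or duplicate candidates are
    regenerated with a fresh derived seed.
    """
    seqs: dict[tuple, str] = {}
    out = []
    ss = np.random.SeedSequence(seed)
    for frag in catalog:
        key = (frag.length_bp, frag.gc_content, frag.cpg_fraction,
               frag.alternative_index, frag.methylation_status)
        if key not in seqs:
            child = int(ss.spawn(1)[0].generate_state(1)[0] % 2**31)
            for attempt in range(50):
                cand = generate_sequence(frag, child + attempt, max_attempts)
                if cand in seqs.values():
                    continue
                if stem_threshold is not None:
                    ok, _ = screen_secondary_structure(cand, stem_threshold)
                    if not ok:
                        continue
                if reference_kmers is not None:
                    if not screen_genome_match_kmers(cand, reference_kmers, k):
                        continue
                seqs[key] = cand
                break
            else:
                raise GenerationError(
                    f"{frag.id}: no candidate passed the screens"
                )
        out.append(replace(frag, sequence=seqs[key]))
    return FragmentCatalog(out, catalog.pool_total_mass_ng,
                           dict(catalog.known_amounts))


# ---------------------------------------------------------------------------
# screens


def reverse_complement(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


def screen_secondary_structure(
    sequence: str, stem_threshold: int = 10, min_loop: int = 3
) -> tuple[bool, int]:
    """Hairpin screen: find the longest perfect inverted-repeat stem.

    A stem of length s with outer pair (i, j) pairs sequence[i:i+s] with
    the reverse complement of sequence[j-s+1:j+1], leaving a loop of
    j-i+1-2s >= min_loop unpaired bases.  Returns (pass, longest stem);
    pass is False when the stem reaches ``stem_threshold``.
    """
    if not sequence:
        raise ValueError("empty sequence")
    n = len(sequence)
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    # f[i][j] = run of complementary outer pairs ending at (i, j)
    best = 0
    prev = [0] * (n + 1)  # row i+1
    for i in range(n - 1, -1, -1):
        cur = [0] * (n + 1)
        ci = comp.get(sequence[i])
        for j in range(n - 1, i, -1):
            if sequence[j] == ci:
                run = prev[j - 1] + 1  # inner pair is (i+1, j-1)
                cur[j] = run
                usable = min(run, (j - i + 1 - min_loop) // 2)
                if usable > best:
                    best = usable
        prev = cur
    return best < stem_threshold, best


def screen_genome_match(
    sequence: str, reference_sequences, k: int = 25
) -> bool:
    """Genome-uniqueness screen: pass iff no k-mer of ``sequence`` occurs
    in the reference (either strand).  ``k=25`` approximates a blastn
    bit score of 50 (~25 matched bases)."""
    kmers = reference_kmer_set(reference_sequences, k)
    return screen_genome_match_kmers(sequence, kmers, k)


def screen_genome_match_kmers(
    sequence: str, reference_kmers: set[str], k: int = 25
) -> bool:
    if k > len(sequence):
        raise ValueError(f"k={k} exceeds sequence length {len(sequence)}")
    for i in range(len(sequence) - k + 1):
        if sequence[i : i + k] in reference_kmers:
            return False
    return True


def reference_kmer_set(reference_sequences, k: int = 25) -> set[str]:
    """Index both strands of reference sequences as a k-mer set."""
    if isinstance(reference_sequences, str):
        reference_sequences = [reference_sequences]
    kmers: set[str] = set()
    for ref in reference_sequences:
        ref = str(ref).upper()
        for s in (ref, reverse_complement(ref)):
            for i in range(len(s) - k + 1):
                kmers.add(s[i : i + k])
    return kmers


# ---------------------------------------------------------------------------
# pooling


def molecular_mass_ds(sequence: str) -> float:
    """Molecular mass (g/mol) of the double-stranded fragment, from base
    composition with standard monophosphate residue masses per strand."""
    fwd = sum(_NT_MASS[b] for b in sequence) + _END_CORRECTION
    rev = sum(_NT_MASS[b] for b in reverse_complement(sequence)) + _END_CORRECTION
    return fwd + rev


def equimolar_amounts(
    catalog: FragmentCatalog,
    total_mass_ng: float | None = None,
    scheme: str = "global",
) -> dict[str, float]:
    """Per-fragment molar amounts (pmol) for an equimolar pool.

    ``global``: one molar amount for every fragment, chosen so the pool
    masses sum to ``total_mass_ng``.  ``per-length-pool``: total mass is
    split equally across the three length pools; fragments are equimolar
    within each pool.  1 ng at mass M g/mol is 1e3/M pmol.
    """
    if total_mass_ng is None:
        total_mass_ng = catalog.pool_total_mass_ng
    masses = {}
    for f in catalog:
        m = f.molecular_mass
        if m is None:
            raise DesignError(f"{f.id}: sequence required to compute mass")
        masses[f.id] = m
    amounts: dict[str, float] = {}
    if scheme == "global":
        groups = [list(masses)]
        group_mass = [total_mass_ng]
    elif scheme == "per-length-pool":
        lengths = sorted({f.length_bp for f in catalog})
        groups = [
            [f.id for f in catalog if f.length_bp == L] for L in lengths
        ]
        group_mass = [total_mass_ng / len(lengths)] * len(lengths)
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    for ids, mass_ng in zip(groups, group_mass):
        total_molar_mass = sum(masses[i] for i in ids)  # g/mol summed
        pmol = 1e3 * mass_ng / total_molar_mass
        for i in ids:
            amounts[i] = pmol
    return amounts


def assign_amounts(
    catalog: FragmentCatalog,
    total_mass_ng: float | None = None,
    scheme: str = "global",
) -> FragmentCatalog:
    """Return a catalog with known_amounts filled by ``equimolar_amounts``."""
    amounts = equimolar_amounts(catalog, total_mass_ng, scheme)
    return FragmentCatalog(
        list(catalog.fragments),
        total_mass_ng if total_mass_ng is not None else catalog.pool_total_mass_ng,
        amounts,
    )


# ---------------------------------------------------------------------------
# catalog I/O


def write_catalog_tsv(catalog: FragmentCatalog, path) -> None:
    catalog.to_frame().to_csv(path, sep="\t", index=False)


def read_catalog_tsv(path) -> FragmentCatalog:
    df = pd.read_csv(path, sep="\t")
    frags = []
    amounts = {}
    for _, r in df.iterrows():
        frags.append(
            FragmentSpec(
                id=r["id"],
                length_bp=int(r["length_bp"]),
                gc_content=float(r["gc_content"]),
                cpg_fraction=float(r["cpg_fraction"]),
                methylation_status=r["methylation_status"],
                alternative_index=int(r["alternative_index"]),
                sequence=r["sequence"] if "sequence" in df.columns
                and isinstance(r.get("sequence"), str) else None,
                synthesis_ok=bool(r["synthesis_ok"]),
            )
        )
        if "amount_pmol" in df.columns and pd.notna(r["amount_pmol"]):
            amounts[r["id"]] = float(r["amount_pmol"])
    return FragmentCatalog(frags, known_amounts=amounts)


def write_catalog_fasta(catalog: FragmentCatalog, path) -> None:
    """Write spike-in sequences as FASTA; contig names double as the
    alignment reference names for the composite reference."""
    with open(path, "w") as fh:
        for f in catalog:
            if f.sequence is None:
                raise DesignError(f"{f.id}: no sequence to write")
            fh.write(f">{f.id}\n{f.sequence}\n")
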