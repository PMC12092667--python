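"""Synthetic amplicon reads and screen count matrices with known ground truth.

Two generators are provided:

* :func:`simulate_reads` draws editing-outcome alleles from a multinomial
  over user-declared categories (single C->T, C->G, C->A, dual/mixed edits,
  indels, WT) at a target site, applies per-base sequencing error, and
  returns FASTQ-style records together with a per-read truth table.

* :func:`simulate_screen` draws negative-binomial sgRNA counts for the bulk
  and FACS-sorted populations of a pooled CRISPRi screen, with a gene-effect
  model linking knockdown to reporter-conversion probability.  The default
  library mirrors the screen's design: 2015 genes x 5 sgRNAs + 2243
  non-targeting controls (12,318 sgRNAs), baseline sorted fraction
  pi0 = 0.132 and >=200x depth per sgRNA.

Everything is driven by a single ``numpy`` Generator so identical
configurations and seeds give byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .sites import FORWARD, REVERSE, TargetSite

__all__ = [
    "TargetSite",
    "OutcomeCategory",
    "OutcomeSpec",
    "LibrarySpec",
    "SimConfig",
    "make_default_sites",
    "nc_like_outcome_spec",
    "simulate_reads",
    "simulate_screen",
    "default_library_spec",
]

NONTARGETING = "NONTARGETING"

WT = "WT"
INDEL = "indel"


# ---------------------------------------------------------------------------
# outcome specification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OutcomeCategory:
    """One mutually exclusive editing outcome.

    ``edits`` maps a 1-based protospacer target-C position to the base read
    there on the protospacer strand; positions omitted stay ``C``.  The two
    special labels ``"WT"`` (no edits) and ``"indel"`` have no ``edits``.
    """

    label: str
    frequency: float
    edits: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.frequency <= 1.0:
            raise ValueError(f"category {self.label!r}: frequency outside [0, 1]")
        for pos, base in self.edits.items():
            if base not in "ACGT":
                raise ValueError(f"category {self.label!r}: base {base!r} at {pos}")


@dataclass(frozen=True)
class OutcomeSpec:
    """A multinomial over outcome categories; frequencies must sum to 1."""

    categories: tuple[OutcomeCategory, ...]

    def __post_init__(self) -> None:
        total = sum(c.frequency for c in self.categories)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"category frequencies sum to {total!r}, not 1")
        labels = [c.label for c in self.categories]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate category labels")
        if WT not in labels:
            raise ValueError("an explicit WT category is required")

    @property
    def labels(self) -> list[str]:
        return [c.label for c in self.categories]


def outcome_spec(freqs: dict[str, float],
                 edits: dict[str, dict[int, str]] | None = None) -> OutcomeSpec:
    """Build an :class:`OutcomeSpec` from ``{label: frequency}``.

    Labels of the form ``"T@10"`` or ``"T@10|G@14"`` are parsed into edits
    automatically; ``edits`` can override or add mappings.
    """
    edits = dict(edits or {})
    cats = []
    for label, f in freqs.items():
        if label in (WT, INDEL):
            cats.append(OutcomeCategory(label, f))
            continue
        if label in edits:
            e = edits[label]
        else:
            e = {}
            for token in label.split("|"):
                base, _, pos = token.partition("@")
                e[int(pos)] = base
        e = {p: b for p, b in e.items() if b != "C"}
        cats.append(OutcomeCategory(label, f, e))
    return OutcomeSpec(tuple(cats))


def nc_like_outcome_spec(site: TargetSite,
                         ct: float = 0.156, cg: float = 0.066,
                         ca: float = 0.013, indel: float = 0.02) -> OutcomeSpec:
    """Negative-control-like outcome mix at the site's first target C.

    Defaults follow the non-targeting-control editing profile of the
    C->T reporter: 15.6% C->T, 6.6% C->G, with a small C->A fraction (the
    least frequent point-mutation outcome) and a 2% indel fraction.
    """
    pos = site.target_c_positions[0]
    return outcome_spec({
        f"T@{pos}": ct,
        f"G@{pos}": cg,
        f"A@{pos}": ca,
        INDEL: indel,
        WT: 1.0 - ct - cg - ca - indel,
    })


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimConfig:
    """Simulation knobs shared by the read and screen generators.

    ``depth_per_sgrna`` defaults to 200 reads, the screen's minimum
    sequencing coverage; ``error_rate`` is the per-base substitution error.
    """

    n_reads: int = 10_000
    error_rate: float = 0.001
    depth_per_sgrna: float = 200.0
    nb_dispersion: float = 0.05
    library_skew_sigma: float = 0.3
    essential_depletion: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reads <= 0 or self.depth_per_sgrna <= 0:
            raise ValueError("n_reads and depth_per_sgrna must be positive")
        if not 0.0 <= self.error_rate < 0.05:
            raise ValueError("error_rate must be in [0, 0.05)")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be non-negative")


@dataclass(frozen=True)
class LibrarySpec:
    """CRISPRi library layout and per-gene effects.

    ``effect_map`` multiplies the baseline reporter-conversion probability
    ``pi0`` for every sgRNA of that gene (1.0 = no effect); genes flagged in
    ``essential_flags`` are additionally depleted in all day-13 populations.
    """

    n_genes: int = 2015
    sgrnas_per_gene: int = 5
    n_nontargeting: int = 2243
    pi0: float = 0.132
    effect_map: dict[str, float] = field(default_factory=dict)
    essential_flags: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_genes < 2:
            raise ValueError("need at least 2 genes")
        if self.sgrnas_per_gene < 1 or self.n_nontargeting < 0:
            raise ValueError("invalid library dimensions")
        if not 0.0 < self.pi0 < 1.0:
            raise ValueError("pi0 must be in (0, 1)")
        for g, m in self.effect_map.items():
            if m < 0:
                raise ValueError(f"effect multiplier for {g} must be >= 0")

    @property
    def total_sgrnas(self) -> int:
        return self.n_genes * self.sgrnas_per_gene + self.n_nontargeting

    @property
    def genes(self) -> list[str]:
        return [f"GENE{i:05d}" for i in range(1, self.n_genes + 1)]


def default_library_spec(**overrides) -> LibrarySpec:
    """The screen's library: 2015 genes x 5 sgRNAs + 2243 non-targeting."""
    return LibrarySpec(**overrides)


# ---------------------------------------------------------------------------
# default sites
# ---------------------------------------------------------------------------

def _filler(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


def _proto_without_bystanders(rng: np.random.Generator, length: int,
                              c_positions: tuple[int, ...]) -> str:
    """A protospacer with C exactly at ``c_positions`` (no bystander Cs)."""
    bases = []
    for p in range(1, length + 1):
        if p in c_positions:
            bases.append("C")
        else:
            bases.append(rng.choice(list("AGT")))
    return "".join(bases)


def _embed(rng: np.random.Generator, proto: str, flank5: int, flank3: int,
           pam: str = "TTGAAT") -> tuple[str, int]:
    """Embed a forward-strand protospacer + 3' PAM between random flanks."""
    left = _filler(rng, flank5)
    right = _filler(rng, flank3)
    return left + proto + pam + right, flank5


def make_default_sites(seed: int = 2025) -> list[TargetSite]:
    """Synthetic stand-in target sites with the study's geometry.

    Returns three sites: a reporter-like site whose editing window contains
    exactly one target C (the reporters were codon-optimised to remove
    bystander cytosines), a HEK3-like site with target Cs at protospacer
    positions 10 and 16, and an RNF2-like site with target Cs at positions
    10 and 14 (placed on the amplicon-reverse strand to exercise both
    orientations).  Sequences are synthetic; real sites can be supplied via
    site files.
    """
    rng = np.random.default_rng(seed)

    proto = _proto_without_bystanders(rng, 21, (10,))
    amp, start = _embed(rng, proto, 90, 90)
    reporter = TargetSite("reporter_like", amp, start, 21, FORWARD, (10,))

    proto = _proto_without_bystanders(rng, 21, (10, 16))
    amp, start = _embed(rng, proto, 80, 100)
    hek3 = TargetSite("HEK3_like", amp, start, 21, FORWARD, (10, 16))

    proto = _proto_without_bystanders(rng, 21, (10, 14))
    amp_fwd, start = _embed(rng, proto, 70, 110)
    from .sites import reverse_complement
    amp = reverse_complement(amp_fwd)
    start_rev = len(amp) - start - 21
    rnf2 = TargetSite("RNF2_like", amp, start_rev, 21, REVERSE, (10, 14))

    return [reporter, hek3, rnf2]


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------

def _apply_category(site: TargetSite, cat: OutcomeCategory,
                    rng: np.random.Generator) -> str:
    """Build the (error-free) allele sequence for one outcome category."""
    amp = site.amplicon
    if cat.label == INDEL:
        lo, hi = site.window_bounds()
        if rng.random() < 0.5:
            length = int(rng.integers(1, 11))      # deletion of 1-10 nt
            start_min = max(1, lo - length + 1)
            start_max = min(hi, len(amp) - length - 1)
            if start_max < start_min:
                raise ValueError(f"{site.site_id}: deletion does not fit inside the amplicon")
            start = int(rng.integers(start_min, start_max + 1))
            return amp[:start] + amp[start + length:]
        length = int(rng.integers(1, 4))           # insertion of 1-3 nt
        pos = int(rng.integers(lo + 1, hi + 1))
        ins = _filler(rng, length)
        return amp[:pos] + ins + amp[pos:]
    seq = list(amp)
    for proto_pos, base in cat.edits.items():
        seq[site.amplicon_index(proto_pos)] = site.to_amplicon_strand(base)
    return "".join(seq)


_BASES = np.frombuffer(b"ACGT", dtype="S1")


def _sequencing_errors(seq: str, error_rate: float,
                       rng: np.random.Generator) -> str:
    if error_rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hits = np.nonzero(rng.random(arr.size) < error_rate)[0]
    for i in hits:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = choices[rng.integers(0, 3)]
    return arr.tobytes().decode()


def simulate_reads(site: TargetSite, spec: OutcomeSpec, cfg: SimConfig,
                   rng: np.random.Generator | None = None,
                   ) -> tuple[list[tuple[str, str, str]], pd.DataFrame]:
    """Simulate amplicon reads for one site.

    Category counts are multinomial(``cfg.n_reads``, frequencies); each read
    is the amplicon with the category's substitutions (or a sampled indel)
    applied, then per-base substitution errors.  Quality strings are constant
    Q30.

    Returns
    -------
    reads
        List of ``(read_id, sequence, quality)`` records.
    truth
        DataFrame with columns ``read_id`` and ``category``.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    freqs = np.array([c.frequency for c in spec.categories])
    counts = rng.multinomial(cfg.n_reads, freqs)

    reads: list[tuple[str, str, str]] = []
    truth_rows: list[tuple[str, str]] = []
    idx = 0
    for cat, n in zip(spec.categories, counts):
        # substitution alleles are identical within a category; build once
        template = None if cat.label == INDEL else _apply_category(site, cat, rng)
        for _ in range(int(n)):
            seq = _apply_category(site, cat, rng) if template is None else template
            seq = _sequencing_errors(seq, cfg.error_rate, rng)
            rid = f"{site.site_id}:r{idx:07d}"
            reads.append((rid, seq, "?" * len(seq)))   # '?' = Q30, Phred+33
            truth_rows.append((rid, cat.label))
            idx += 1
    order = rng.permutation(len(reads))
    reads = [reads[i] for i in order]
    truth = pd.DataFrame([truth_rows[i] for i in order],
                         columns=["read_id", "category"])
    return reads, truth


# ---------------------------------------------------------------------------
# screen simulation
# ---------------------------------------------------------------------------

def _nb_draw(rng: np.random.Generator, mean: np.ndarray,
             dispersion: float) -> np.ndarray:
    """Negative binomial with var = mu + dispersion * mu^2 (Poisson at 0)."""
    mean = np.asarray(mean, dtype=float)
    if dispersion < 1e-12:
        return rng.poisson(mean)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def simulate_screen(lib: LibrarySpec, cfg: SimConfig, n_replicates: int = 2,
                    rng: np.random.Generator | None = None,
                    ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate bulk and sorted sgRNA count matrices for a pooled screen.

    Per sgRNA *s* of gene *g* the reporter-conversion probability is
    ``pi_s = min(1, pi0 * effect_map[g])``.  Bulk counts are NB with mean
    ``depth * w_s`` (lognormal library-skew weights ``w_s``); sorted counts
    redistribute the same total depth proportionally to ``w_s * pi_s`` (and
    the essential-gene day-13 depletion factor, which also scales the day-13
    bulk populations).  The truth table records the closed-form expected
    sorted-vs-bulk log2 fold change ``log2(pi_s / pi_bar)``.

    Returns ``(bulk, sorted, truth)`` data frames; bulk holds the per
    replicate ``day0``, ``bulk_nodox`` and ``bulk_dox`` samples.
    """
    if lib.n_genes < 2:
        raise ValueError("need at least 2 genes")
    if cfg.depth_per_sgrna <= 0:
        raise ValueError("depth must be positive")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)

    genes = lib.genes
    sgrnas, sg_gene = [], []
    for g in genes:
        for i in range(1, lib.sgrnas_per_gene + 1):
            sgrnas.append(f"{g}_sg{i}")
            sg_gene.append(g)
    for i in range(1, lib.n_nontargeting + 1):
        sgrnas.append(f"NT_sg{i:05d}")
        sg_gene.append(NONTARGETING)
    n = len(sgrnas)
    sg_gene = np.array(sg_gene)

    effect = np.array([lib.effect_map.get(g, 1.0) for g in sg_gene])
    essential = np.array([bool(lib.essential_flags.get(g, False)) for g in sg_gene])
    pi = np.minimum(1.0, lib.pi0 * effect)

    w = rng.lognormal(mean=0.0, sigma=cfg.library_skew_sigma, size=n)
    depth = cfg.depth_per_sgrna
    day13_weight = np.where(essential, cfg.essential_depletion, 1.0)

    bulk_mean_day0 = depth * w
    bulk_mean_day13 = depth * w * day13_weight
    sorted_share = w * day13_weight * pi
    sorted_mean = depth * n * sorted_share / sorted_share.sum()

    bulk = pd.DataFrame({"sgrna": sgrnas, "gene": sg_gene})
    sorted_df = pd.DataFrame({"sgrna": sgrnas, "gene": sg_gene})
    for r in range(1, n_replicates + 1):
        bulk[f"day0_r{r}"] = _nb_draw(rng, bulk_mean_day0, cfg.nb_dispersion)
        bulk[f"bulk_nodox_r{r}"] = _nb_draw(rng, bulk_mean_day13, cfg.nb_dispersion)
        bulk[f"bulk_dox_r{r}"] = _nb_draw(rng, bulk_mean_day13, cfg.nb_dispersion)
        sorted_df[f"sorted_r{r}"] = _nb_draw(rng, sorted_mean, cfg.nb_dispersion)

    pi_bar = float(sorted_share.sum() / (w * day13_weight).sum())
    with np.errstate(divide="ignore"):
        expected_lfc = np.log2(pi / pi_bar)
    truth = pd.DataFrame({
        "sgrna": sgrnas,
        "gene": sg_gene,
        "weight": w,
        "pi": pi,
        "effect": effect,
        "essential": essential,
        "expected_lfc": expected_lfc,
    })
    return bulk, sorted_df, truth
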