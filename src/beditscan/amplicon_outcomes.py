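"""Allele-level editing-outcome calls from amplicon reads.

Each read is globally aligned to the reference amplicon with affine gap
penalties, classified into a mutually exclusive outcome taxonomy at the
site's target cytosines (indel > per-target-C base calls > WT), and the
classified reads are aggregated into absolute (percent of all classified
reads) and relative (percent of edited reads) efficiencies.

Classification precedence within the quantification window (nick-centred,
halfwidth 10 by default):

1. any alignment gap overlapping the window -> ``indel``;
2. otherwise the base calls at the target C positions, reported on the
   protospacer strand, form the allele key (e.g. ``"T@10|C@16"``);
3. reads whose only window substitutions are at non-target positions are
   counted in totals but flagged ``other-edit`` and excluded from the joint
   taxonomy.

Reads whose alignment does not cover the window are dropped (tallied), and
reads scoring below a configurable fraction of the perfect score are marked
unalignable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from Bio import Align

from .sites import TargetSite

__all__ = [
    "AlignScoring",
    "AlignedRead",
    "ReadClass",
    "OutcomeProfile",
    "align_read",
    "classify_read",
    "aggregate",
    "call_outcomes",
]

WT = "WT"
INDEL = "indel"
OTHER_EDIT = "other-edit"


@dataclass(frozen=True)
class AlignScoring:
    """Affine-gap scoring: a gap of length L costs open + (L-1)*extend."""

    match: float = 2.0
    mismatch: float = -3.0
    gap_open: float = -10.0
    gap_extend: float = -1.0
    min_score_fraction: float = 0.6


@dataclass
class AlignedRead:
    """Per-reference-position view of a global read-vs-amplicon alignment.

    ``ref_calls`` holds, for every reference position, the read base aligned
    there (``"-"`` for a deletion); positions outside ``span`` are not
    covered by the read.  ``insertions`` lists ``(ref_pos, seq)`` for read
    bases inserted before ``ref_pos``.
    """

    score: float
    ref_calls: str
    span: tuple[int, int]                      # [start, end) covered ref range
    insertions: list[tuple[int, str]] = field(default_factory=list)
    alignable: bool = True

    def deletion_spans(self) -> list[tuple[int, int]]:
        """Interior deletion runs as [start, end) reference intervals."""
        spans = []
        start = None
        for i in range(self.span[0], self.span[1]):
            if self.ref_calls[i] == "-":
                if start is None:
                    start = i
            elif start is not None:
                spans.append((start, i))
                start = None
        if start is not None:
            spans.append((start, self.span[1]))
        return spans


def _aligner(scoring: AlignScoring) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = scoring.match
    aligner.mismatch_score = scoring.mismatch
    aligner.open_gap_score = scoring.gap_open
    aligner.extend_gap_score = scoring.gap_extend
    return aligner


def align_read(read: str, site: TargetSite,
               scoring: AlignScoring = AlignScoring()) -> AlignedRead:
    """Globally align a read to the site's amplicon.

    Equal-length reads with at most 4 mismatches take an ungapped fast path:
    with these penalties a gapped global alignment of equal-length sequences
    requires two gap openings (cost >= 22 > 4 substitutions at 5 each), so
    the ungapped alignment is provably optimal.
    """
    if not read:
        raise ValueError("empty read")
    read = read.upper()
    ref = site.amplicon
    perfect = scoring.match * min(len(read), len(ref))

    if len(read) == len(ref):
        mism = sum(a != b for a, b in zip(read, ref))
        if mism <= 4:
            score = scoring.match * (len(ref) - mism) + scoring.mismatch * mism
            return AlignedRead(score=score, ref_calls=read, span=(0, len(ref)),
                               alignable=score >= scoring.min_score_fraction * perfect)

    aln = _aligner(scoring).align(ref, read)[0]
    score = aln.score
    calls = ["-"] * len(ref)
    insertions: list[tuple[int, str]] = []
    blocks_t, blocks_q = aln.aligned
    prev_t = prev_q = None
    for (t0, t1), (q0, q1) in zip(blocks_t, blocks_q):
        if prev_q is not None and q0 > prev_q:
            insertions.append((t0, read[prev_q:q0]))
        calls[t0:t1] = list(read[q0:q1])
        prev_t, prev_q = t1, q1
    span = (int(blocks_t[0][0]), int(blocks_t[-1][1])) if len(blocks_t) else (0, 0)

    # alignability discounts terminal gaps so a clean but truncated read is
    # judged on its aligned part (window coverage then decides 'dropped')
    def _gap(length: int) -> float:
        return scoring.gap_open + (length - 1) * scoring.gap_extend if length else 0.0

    adjusted = score - _gap(span[0]) - _gap(len(ref) - span[1])
    if len(blocks_q):
        adjusted -= _gap(int(blocks_q[0][0]))
        adjusted -= _gap(len(read) - int(blocks_q[-1][1]))
    return AlignedRead(score=score, ref_calls="".join(calls), span=span,
                       insertions=insertions,
                       alignable=adjusted >= scoring.min_score_fraction * perfect)


@dataclass(frozen=True)
class ReadClass:
    """Outcome call for a single read."""

    status: str          # classified | other_edit | dropped | unalignable
    key: str | None      # allele key, "indel", or None when not classified
    indel: bool = False
    indel_spans: tuple[tuple[int, int], ...] = ()


def classify_read(aln: AlignedRead, site: TargetSite) -> ReadClass:
    """Classify an aligned read into the outcome taxonomy (see module doc)."""
    if not aln.alignable:
        return ReadClass("unalignable", None)
    lo, hi = site.window_bounds()
    if aln.span[0] > lo or aln.span[1] < hi + 1:
        return ReadClass("dropped", None)

    spans = [s for s in aln.deletion_spans() if s[0] <= hi and s[1] > lo]
    # insertions abutting either window edge count as in-window (equivalent
    # optimal placements can shift an insertion along a repeat)
    spans += [(p, p) for p, _ in aln.insertions if lo <= p <= hi + 1]
    if spans:
        return ReadClass("classified", INDEL, indel=True,
                         indel_spans=tuple(sorted(spans)))

    calls = {p: site.to_protospacer_strand(aln.ref_calls[site.amplicon_index(p)])
             for p in site.target_c_positions}
    key = "|".join(f"{calls[p]}@{p}" for p in site.target_c_positions)
    if any(b != "C" for b in calls.values()):
        return ReadClass("classified", key)

    target_idx = {site.amplicon_index(p) for p in site.target_c_positions}
    for i in range(lo, hi + 1):
        if i not in target_idx and aln.ref_calls[i] != site.amplicon[i]:
            return ReadClass("other_edit", None)
    return ReadClass("classified", key)


@dataclass
class OutcomeProfile:
    """Absolute and relative editing efficiencies per outcome category.

    ``absolute`` percentages are over all classified reads (the mutually
    exclusive joint taxonomy plus WT sums to 100); ``relative`` percentages
    are over edited reads only and are ``None`` when nothing is edited.
    ``marginal_absolute`` gives per-position C->T/G/A conversion marginals
    summed over the joint categories containing that conversion.
    """

    counts: dict[str, int]
    n_classified: int
    n_other_edit: int
    n_dropped: int
    n_unalignable: int
    absolute: dict[str, float]
    relative: dict[str, float] | None
    marginal_absolute: dict[int, dict[str, float]]
    total_editing: float

    @property
    def n_total(self) -> int:
        return (self.n_classified + self.n_other_edit
                + self.n_dropped + self.n_unalignable)


def _is_wt_key(key: str, site: TargetSite) -> bool:
    if key == WT:
        return True
    if key == INDEL:
        return False
    return all(tok.startswith("C@") for tok in key.split("|"))


def aggregate(counts: dict[str, int], site: TargetSite,
              n_other_edit: int = 0, n_dropped: int = 0,
              n_unalignable: int = 0,
              include_indels_in_edited: bool = True) -> OutcomeProfile:
    """Aggregate per-allele counts into an :class:`OutcomeProfile`.

    ``counts`` maps allele keys (plus ``"indel"``) to read counts; WT-like
    keys (all target positions C) are pooled under ``"WT"``.
    """
    pooled: dict[str, int] = {}
    for key, n in counts.items():
        label = WT if _is_wt_key(key, site) else key
        pooled[label] = pooled.get(label, 0) + int(n)
    total = sum(pooled.values())
    if total == 0:
        raise ValueError("no classified reads to aggregate")

    absolute = {k: 100.0 * n / total for k, n in pooled.items()}

    edited_keys = [k for k in pooled if k != WT]
    if not include_indels_in_edited:
        edited_keys = [k for k in edited_keys if k != INDEL]
    n_edited = sum(pooled[k] for k in edited_keys)
    relative = ({k: 100.0 * pooled[k] / n_edited for k in edited_keys}
                if n_edited else None)

    marginal: dict[int, dict[str, float]] = {
        p: {"T": 0.0, "G": 0.0, "A": 0.0} for p in site.target_c_positions}
    for key, pct in absolute.items():
        if key in (WT, INDEL):
            continue
        for tok in key.split("|"):
            base, _, pos = tok.partition("@")
            if base in "TGA":
                marginal[int(pos)][base] += pct

    total_editing = 100.0 * sum(pooled[k] for k in pooled if k != WT) / total
    return OutcomeProfile(
        counts=pooled, n_classified=total, n_other_edit=n_other_edit,
        n_dropped=n_dropped, n_unalignable=n_unalignable,
        absolute=absolute, relative=relative,
        marginal_absolute=marginal, total_editing=total_editing)


def call_outcomes(reads, site: TargetSite,
                  scoring: AlignScoring = AlignScoring(),
                  include_indels_in_edited: bool = True,
                  min_mean_quality: float | None = None,
                  ) -> tuple[pd.DataFrame, OutcomeProfile]:
    """End-to-end outcome calling: align, classify, and aggregate.

    Parameters
    ----------
    reads
        Iterable of ``(read_id, sequence, quality)`` records.  No quality
        filtering is applied by default; with ``min_mean_quality`` set,
        reads whose mean Phred quality (Phred+33) falls below it are
        counted as dropped.

    Returns
    -------
    allele_table
        DataFrame with ``allele_key``, ``indel_flag``, ``n_reads`` and
        ``pct_reads`` (percent of classified reads), sorted by count.
    profile
        The aggregated :class:`OutcomeProfile`.
    """
    counts: dict[str, int] = {}
    indel_flags: dict[str, bool] = {}
    n_other = n_dropped = n_unalignable = n_total = 0
    for _, seq, qual in reads:
        n_total += 1
        if min_mean_quality is not None and qual:
            mean_q = sum(qual.encode()) / len(qual) - 33
            if mean_q < min_mean_quality:
                n_dropped += 1
                continue
        cls = classify_read(align_read(seq, site, scoring), site)
        if cls.status == "classified":
            counts[cls.key] = counts.get(cls.key, 0) + 1
            indel_flags[cls.key] = cls.indel
        elif cls.status == "other_edit":
            n_other += 1
        elif cls.status == "dropped":
            n_dropped += 1
        else:
            n_unalignable += 1
    if n_total == 0:
        raise ValueError("no reads supplied: empty FASTQ?")
    if not counts:
        raise ValueError("no reads could be classified at this site")

    profile = aggregate(counts, site, n_other_edit=n_other, n_dropped=n_dropped,
                        n_unalignable=n_unalignable,
                        include_indels_in_edited=include_indels_in_edited)
    n_classified = sum(counts.values())
    table = pd.DataFrame(
        [(k, indel_flags[k], n, 100.0 * n / n_classified)
         for k, n in sorted(counts.items(), key=lambda kv: -kv[1])],
        columns=["allele_key", "indel_flag", "n_reads", "pct_reads"])
    return table, profile
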