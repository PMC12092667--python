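"""Target-site geometry for base-editing amplicons.

A :class:`TargetSite` describes an amplicon together with the protospacer a
Cas9n-deaminase editor is directed to.  Protospacer positions are counted
1-based from the PAM-distal 5' end of the protospacer (so "C10" is the tenth
base), with the PAM 3' of the protospacer.  The protospacer may lie on either
strand of the amplicon; base calls are always reported on the protospacer
strand.

The quantification window is centred on the protospacer base immediately 5'
of the Cas9n nick on the sgRNA-complementary strand (``nick_offset``, default
between positions 17 and 18, i.e. 3 bp 5' of the PAM for a 20-21 nt
protospacer) and extends ``window_halfwidth`` bases to each side.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = ["TargetSite", "reverse_complement", "FORWARD", "REVERSE"]

FORWARD = "amplicon_forward"
REVERSE = "amplicon_reverse"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def complement(base: str) -> str:
    return base.translate(_COMPLEMENT)


@dataclass(frozen=True)
class TargetSite:
    """An editing target: amplicon, protospacer geometry and target cytosines.

    Parameters
    ----------
    site_id
        Short label for the site.
    amplicon
        Reference amplicon sequence (A/C/G/T, typically 100-400 nt).
    protospacer_start
        0-based offset of the protospacer within the amplicon (the offset of
        the amplicon-forward slice that the protospacer occupies, regardless
        of strand).
    protospacer_len
        Protospacer length in nt (20 or 21).
    strand
        ``"amplicon_forward"`` if the protospacer reads off the amplicon
        as given, ``"amplicon_reverse"`` if it is the reverse complement.
    target_c_positions
        1-based protospacer positions (from the PAM-distal 5' end) carrying
        the target cytosines, e.g. ``(10, 16)``.
    nick_offset
        1-based protospacer position immediately 5' of the Cas9n nick on the
        sgRNA-complementary strand.
    window_halfwidth
        Half-width of the quantification window, in bases around the nick.
    """

    site_id: str
    amplicon: str
    protospacer_start: int
    protospacer_len: int
    strand: str
    target_c_positions: tuple[int, ...]
    nick_offset: int = 17
    window_halfwidth: int = 10
    pam_side: str = field(default="three_prime")

    def __post_init__(self) -> None:
        amp = self.amplicon.upper()
        object.__setattr__(self, "amplicon", amp)
        object.__setattr__(self, "target_c_positions",
                           tuple(sorted(int(p) for p in self.target_c_positions)))
        if not amp or set(amp) - set("ACGT"):
            raise ValueError(f"{self.site_id}: amplicon must be a non-empty A/C/G/T string")
        if self.protospacer_len not in (20, 21):
            raise ValueError(f"{self.site_id}: protospacer_len must be 20 or 21")
        if self.strand not in (FORWARD, REVERSE):
            raise ValueError(f"{self.site_id}: strand must be {FORWARD!r} or {REVERSE!r}")
        if self.pam_side != "three_prime":
            raise ValueError(f"{self.site_id}: only 3'-PAM editors are supported")
        if not (0 <= self.protospacer_start
                and self.protospacer_start + self.protospacer_len <= len(amp)):
            raise ValueError(f"{self.site_id}: protospacer does not fit inside the amplicon")
        if not (1 <= self.nick_offset <= self.protospacer_len):
            raise ValueError(f"{self.site_id}: nick_offset outside the protospacer")
        for p in self.target_c_positions:
            if not 1 <= p <= self.protospacer_len:
                raise ValueError(f"{self.site_id}: target C position {p} outside protospacer")
            if self.protospacer_base(p) != "C":
                raise ValueError(
                    f"{self.site_id}: protospacer position {p} is "
                    f"{self.protospacer_base(p)!r}, expected 'C'")
        lo, hi = self.window_bounds()
        if lo < 0 or hi >= len(amp):
            raise ValueError(f"{self.site_id}: quantification window extends outside amplicon")

    # -- coordinate mapping ------------------------------------------------

    @property
    def protospacer(self) -> str:
        """Protospacer sequence, 5'->3' on the protospacer strand."""
        s = self.amplicon[self.protospacer_start:self.protospacer_start + self.protospacer_len]
        return s if self.strand == FORWARD else reverse_complement(s)

    def amplicon_index(self, proto_pos: int) -> int:
        """0-based amplicon index of 1-based protospacer position."""
        if self.strand == FORWARD:
            return self.protospacer_start + proto_pos - 1
        return self.protospacer_start + self.protospacer_len - proto_pos

    def protospacer_base(self, proto_pos: int) -> str:
        """Reference base at a protospacer position, on the protospacer strand."""
        b = self.amplicon[self.amplicon_index(proto_pos)]
        return b if self.strand == FORWARD else complement(b)

    def to_protospacer_strand(self, base: str) -> str:
        """Convert an amplicon-strand base call to the protospacer strand."""
        return base if self.strand == FORWARD else complement(base)

    def to_amplicon_strand(self, base: str) -> str:
        return base if self.strand == FORWARD else complement(base)

    def window_bounds(self) -> tuple[int, int]:
        """Inclusive 0-based amplicon bounds of the quantification window."""
        c = self.amplicon_index(self.nick_offset)
        return c - self.window_halfwidth, c + self.window_halfwidth
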