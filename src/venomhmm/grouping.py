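"""Structure-based grouping of venom peptides.

Spider venom peptides are conventionally organised by their cysteine
scaffold: the arrangement of cysteines (adjacent cysteines merged, e.g.
``C-C-CC-C-C``), the number of residues between consecutive cysteines
(rendered ``C-X(6)-C-X(5)-...``), and the chemical character of the
residues surrounding conserved positions. This module extracts those
descriptors, matches range patterns such as the inhibitor cystine knot
(ICK) spacing, partitions sequence sets into structural conservation
groups, and trims alignments to the core cysteine motif before profile
construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .io_formats import Msa, SequenceRecord

# Residue property classes used for the tertiary grouping criterion.
CHARGED = set("DEKRH")
POLAR_UNCHARGED = set("STNQYC")
HYDROPHOBIC = set("AVLIMFW")
SMALL = set("GP")

PROPERTY_CLASSES = {
    "charged": CHARGED,
    "polar-uncharged": POLAR_UNCHARGED,
    "hydrophobic": HYDROPHOBIC,
    "small": SMALL,
}
_CLASS_ORDER = ["charged", "polar-uncharged", "hydrophobic", "small"]


@dataclass(frozen=True)
class CysteineFramework:
    """Cysteine arrangement with adjacent cysteines merged into one token."""

    tokens: tuple[str, ...]

    def render(self) -> str:
        return "-".join(self.tokens)

    @property
    def cysteine_count(self) -> int:
        return sum(len(t) for t in self.tokens)


@dataclass(frozen=True)
class SpacingSignature:
    """Residue counts between consecutive cysteines."""

    gaps: tuple[int, ...]

    def render(self) -> str:
        if not self.gaps:
            return ""
        parts = ["C"]
        for g in self.gaps:
            if g > 0:
                parts.append(f"X({g})")
            parts.append("C")
        return "-".join(parts)


@dataclass(frozen=True)
class RangePattern:
    """Inter-cysteine spacing constraints with optional flank constraints.

    Each entry of ``gap_ranges`` is an inclusive (min, max) residue count;
    a fixed spacing X(n) is (n, n). ``leading``/``trailing`` constrain the
    number of residues before the first / after the last cysteine when not
    ``None``.
    """

    gap_ranges: tuple[tuple[int, int], ...]
    leading: tuple[int, int] | None = None
    trailing: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        for lo, hi in self.gap_ranges:
            if lo > hi or lo < 0:
                raise ValueError(f"invalid gap range ({lo}, {hi})")
        for flank in (self.leading, self.trailing):
            if flank is not None and (flank[0] > flank[1] or flank[0] < 0):
                raise ValueError(f"invalid flank range {flank}")

    @property
    def cysteine_count(self) -> int:
        return len(self.gap_ranges) + 1


#: The inhibitor cystine knot (ICK) inter-cysteine spacing: six cysteines
#: forming the C1-C4, C2-C5, C3-C6 knot, with the canonical ranges
#: X(6)-C-X(4,6)-C-X(4,9)-C-C-X(2,10)-C-X(3,14)-C-X(1,16).
ICK_PATTERN = RangePattern(
    gap_ranges=((4, 6), (4, 9), (0, 0), (2, 10), (3, 14)),
    leading=(6, 6),
    trailing=(1, 16),
)


def _cys_positions(residues: str) -> list[int]:
    return [i for i, ch in enumerate(residues) if ch == "C"]


def extract_framework(seq: SequenceRecord) -> CysteineFramework:
    """Cysteine framework of a sequence (empty for cysteine-free peptides)."""
    pos = _cys_positions(seq.residues)
    tokens: list[str] = []
    run = 0
    prev = None
    for p in pos:
        if prev is not None and p == prev + 1:
            run += 1
        else:
            if run:
                tokens.append("C" * run)
            run = 1
        prev = p
    if run:
        tokens.append("C" * run)
    return CysteineFramework(tokens=tuple(tokens))


def spacing_signature(seq: SequenceRecord) -> SpacingSignature:
    """Ordered inter-cysteine residue counts (empty for <2 cysteines)."""
    pos = _cys_positions(seq.residues)
    gaps = tuple(b - a - 1 for a, b in zip(pos, pos[1:]))
    return SpacingSignature(gaps=gaps)


def synthesize_from_signature(signature: SpacingSignature,
                              filler: str = "A",
                              leading: int = 0,
                              trailing: int = 0) -> str:
    """Build a sequence realising ``signature`` with ``filler`` residues."""
    parts = [filler * leading, "C"]
    for g in signature.gaps:
        parts.append(filler * g)
        parts.append("C")
    parts.append(filler * trailing)
    return "".join(parts)


def match_pattern(seq: SequenceRecord, pattern: RangePattern) -> bool:
    """True when the cysteine count and every spacing (and constrained
    flank) of ``seq`` fall within ``pattern``."""
    pos = _cys_positions(seq.residues)
    if len(pos) != pattern.cysteine_count:
        return False
    sig = spacing_signature(seq)
    for gap, (lo, hi) in zip(sig.gaps, pattern.gap_ranges):
        if not lo <= gap <= hi:
            return False
    if pattern.leading is not None:
        lead = pos[0]
        if not pattern.leading[0] <= lead <= pattern.leading[1]:
            return False
    if pattern.trailing is not None:
        trail = len(seq.residues) - pos[-1] - 1
        if not pattern.trailing[0] <= trail <= pattern.trailing[1]:
            return False
    return True


def _cc_context_class(residues: str, window: int = 3) -> str | None:
    """Dominant residue class in the +/-window around the first double
    cysteine, or None when the framework has no CC token."""
    idx = residues.find("CC")
    if idx < 0:
        return None
    lo = max(0, idx - window)
    hi = min(len(residues), idx + 2 + window)
    context = [ch for ch in residues[lo:idx] + residues[idx + 2:hi]]
    counts = {name: 0 for name in _CLASS_ORDER}
    for ch in context:
        for name in _CLASS_ORDER:
            if ch in PROPERTY_CLASSES[name]:
                counts[name] += 1
                break
    best = max(_CLASS_ORDER, key=lambda name: (counts[name],
                                               -_CLASS_ORDER.index(name)))
    return best


@dataclass
class StructuralGroup:
    """One structural conservation group of the partition."""

    framework: CysteineFramework
    signature_ranges: RangePattern
    property_profile: str | None
    members: list[str]

    def key(self) -> str:
        return self.framework.render() or "no-framework"


def group_sequences(seqs: list[SequenceRecord],
                    split_on_properties: bool = False
                    ) -> list[StructuralGroup]:
    """Partition sequences into structural conservation groups.

    The grouping key is (i) the cysteine framework rendering, (ii) the
    exact inter-cysteine gap tuple, and, when ``split_on_properties`` is
    set, (iii) the dominant residue class around the first double-cysteine
    token. Cysteine-free sequences form a single "no-framework" group (the
    short linear cationic route). Observed per-gap (min, max) ranges are
    reported for each group.
    """
    if not seqs:
        raise ValueError("no sequences to group")
    buckets: dict[tuple, list[SequenceRecord]] = {}
    order: list[tuple] = []
    for seq in seqs:
        fw = extract_framework(seq)
        sig = spacing_signature(seq)
        prop = _cc_context_class(seq.residues) if split_on_properties else None
        key = (fw.render(), sig.gaps, prop)
        if key not in buckets:
            buckets[key] = []
            order.append(key)
        buckets[key].append(seq)

    groups = []
    for key in order:
        members = buckets[key]
        fw = extract_framework(members[0])
        sigs = [spacing_signature(s).gaps for s in members]
        n_gaps = len(sigs[0])
        ranges = tuple(
            (min(s[i] for s in sigs), max(s[i] for s in sigs))
            for i in range(n_gaps)
        )
        groups.append(StructuralGroup(
            framework=fw,
            signature_ranges=RangePattern(gap_ranges=ranges),
            property_profile=key[2],
            members=[s.seq_id for s in members],
        ))
    return groups


def trim_msa_to_core(msa: Msa) -> Msa:
    """Trim an alignment to its core cysteine motif.

    Keeps the columns from the first to the last conserved-cysteine column
    (a column where more than half the rows carry C), drops fragment rows
    (more than half gaps inside the kept span) and collapses duplicate
    mature peptides (identical ungapped strings).
    """
    n_rows = len(msa.rows)
    cys_cols = [
        c for c in range(msa.width)
        if sum(1 for _sid, row in msa.rows if row[c] == "C") > n_rows / 2
    ]
    if not cys_cols:
        raise ValueError(
            "no conserved cysteine column found; skip trimming for this "
            "(linear peptide) family"
        )
    lo, hi = cys_cols[0], cys_cols[-1] + 1
    kept: list[tuple[str, str]] = []
    seen_peptides: set[str] = set()
    for sid, row in msa.rows:
        span = row[lo:hi]
        if span.count("-") > len(span) / 2:
            continue  # fragment
        peptide = span.replace("-", "")
        if peptide in seen_peptides:
            continue  # duplicate mature peptide
        seen_peptides.add(peptide)
        kept.append((sid, span))
    if not kept:
        raise ValueError("trimming removed every row of the alignment")
    return Msa(name=msa.name, rows=kept)
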