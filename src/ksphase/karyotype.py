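"""Symbolic algebra over ancestral genomic-block karyotypes.

Crucifer comparative cytogenetics describes chromosomes as ordered, signed
strings of 22 conserved ancestral genomic blocks (A–X, with the K–L and M–N
associations each treated as a single block and block W split into halves
Wa/Wb).  This module parses and serializes such karyotypes, applies the
rearrangement operators relevant to post-polyploid descending dysploidy —
whole-genome duplication (WGD), nested chromosome insertion (NCI) and
segmental inversion — and compares a karyotype against an ancestral one to
classify chromosomes as shared or derived and to detect NCI signatures.

Shipped presets: ``ACK_Cardamineae_n8`` (the 8-chromosome ancestral
Cardamineae karyotype) and ``R_aquatica_n15`` (the reconstructed 15-
chromosome complement whose fusion chromosome arose by NCI of an AK2
homeologue into the centromere of an AK8/6 homeologue).
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field, replace

#: The 22-block crucifer alphabet (K–L and M–N as single blocks).
CANONICAL_BLOCKS = (
    "A", "B", "C", "D", "E", "F", "G", "H", "I", "J",
    "K-L", "M-N",
    "O", "P", "Q", "R", "S", "T", "U", "V", "W", "X",
)

_SUBBLOCK_LABELS = {"W"}  # blocks with defined a/b halves


@dataclass(frozen=True)
class GenomicBlock:
    """One signed ancestral block, optionally a defined half (Wa/Wb)."""

    label: str
    sub: str | None = None
    sign: int = 1

    def __post_init__(self):
        if self.label not in CANONICAL_BLOCKS:
            raise ValueError(f"unknown genomic block label {self.label!r}")
        if self.sub is not None and self.label not in _SUBBLOCK_LABELS:
            raise ValueError(f"block {self.label} has no defined sub-blocks")
        if self.sub not in (None, "a", "b"):
            raise ValueError(f"sub-block qualifier must be 'a' or 'b', got {self.sub!r}")
        if self.sign not in (1, -1):
            raise ValueError("sign must be +1 or -1")

    @property
    def content_key(self) -> tuple[str, str | None]:
        """Identity for content comparisons: label + half, sign ignored."""
        return (self.label, self.sub)

    def flipped(self) -> "GenomicBlock":
        return replace(self, sign=-self.sign)

    def __str__(self) -> str:
        s = "-" if self.sign < 0 else ""
        return f"{s}{self.label}{self.sub or ''}"


_TOKEN_RE = re.compile(r"^(-?)((?:K-L)|(?:M-N)|[A-JOPQ-X])([ab])?$")


def parse_block(token: str) -> GenomicBlock:
    m = _TOKEN_RE.match(token)
    if not m:
        raise ValueError(f"malformed block token {token!r}")
    sign = -1 if m.group(1) else 1
    return GenomicBlock(label=m.group(2), sub=m.group(3), sign=sign)


@dataclass(frozen=True)
class ChromosomeModel:
    """Ordered signed blocks with a centromere position.

    ``centromere`` is the number of blocks preceding the centromere
    (0 or len(blocks) means a terminal centromere).
    """

    id: str
    blocks: tuple[GenomicBlock, ...]
    centromere: int

    def __post_init__(self):
        if not self.blocks:
            raise ValueError(f"chromosome {self.id}: needs at least one block")
        if not 0 <= self.centromere <= len(self.blocks):
            raise ValueError(
                f"chromosome {self.id}: centromere index {self.centromere} "
                f"out of range for {len(self.blocks)} blocks"
            )

    @property
    def content(self) -> Counter:
        """Multiset of (label, half) keys, order/orientation-insensitive."""
        return Counter(b.content_key for b in self.blocks)

    @property
    def centromere_is_internal(self) -> bool:
        return 0 < self.centromere < len(self.blocks)

    def __str__(self) -> str:
        parts = [str(b) for b in self.blocks]
        parts.insert(self.centromere, "|")
        return f"{self.id}: " + " ".join(parts) + " ."


@dataclass(frozen=True)
class Karyotype:
    chromosomes: tuple[ChromosomeModel, ...]

    def __post_init__(self):
        ids = [c.id for c in self.chromosomes]
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate chromosome ids: {dup}")

    @property
    def n(self) -> int:
        """Haploid chromosome number."""
        return len(self.chromosomes)

    def __getitem__(self, chrom_id: str) -> ChromosomeModel:
        for c in self.chromosomes:
            if c.id == chrom_id:
                return c
        raise KeyError(chrom_id)

    def ids(self) -> list[str]:
        return [c.id for c in self.chromosomes]


@dataclass(frozen=True)
class KaryotypeEvent:
    kind: str  # WGD | NCI | inversion
    participants: tuple[str, ...]
    inferred: bool = False
    detail: dict = field(default_factory=dict, compare=False)


# ---------------------------------------------------------------------------
# parsing / serialization

def parse_karyotype(text: str) -> Karyotype:
    """Parse the one-chromosome-per-line block-string format.

    ``ID: [-]BLOCK[a|b] ... | ... .`` — ``|`` marks the centromere, a
    trailing ``.`` ends the chromosome, ``#`` starts a comment.
    """
    chromosomes = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if ":" not in line:
            raise ValueError(f"line {lineno}: missing 'ID:' prefix")
        chrom_id, rest = line.split(":", 1)
        chrom_id = chrom_id.strip()
        tokens = rest.split()
        if not tokens or tokens[-1] != ".":
            raise ValueError(f"line {lineno}: chromosome line must end with '.'")
        tokens = tokens[:-1]
        if tokens.count("|") != 1:
            raise ValueError(
                f"line {lineno}: exactly one centromere '|' required, "
                f"found {tokens.count('|')}"
            )
        cent = tokens.index("|")
        try:
            blocks = tuple(parse_block(t) for t in tokens if t != "|")
        except ValueError as exc:
            raise ValueError(f"line {lineno}: {exc}") from exc
        chromosomes.append(
            ChromosomeModel(id=chrom_id, blocks=blocks, centromere=cent)
        )
    return Karyotype(chromosomes=tuple(chromosomes))


def serialize_karyotype(k: Karyotype) -> str:
    return "\n".join(str(c) for c in k.chromosomes) + ("\n" if k.chromosomes else "")


# ---------------------------------------------------------------------------
# rearrangement operators

def whole_genome_duplication(k: Karyotype) -> Karyotype:
    """Duplicate every chromosome; copies get _1/_2 id suffixes."""
    chroms = []
    for c in k.chromosomes:
        for suffix in ("_1", "_2"):
            chroms.append(replace(c, id=c.id + suffix))
    return Karyotype(chromosomes=tuple(chroms))


def nested_chromosome_insertion(
    k: Karyotype,
    recipient_id: str,
    donor_id: str,
    donor_orientation: str = "inverted",
) -> Karyotype:
    """Insert the whole donor chromosome into the recipient's centromere.

    The donor's block string (reversed with flipped signs when
    ``donor_orientation == 'inverted'``) is spliced at the recipient's
    internal centromere; the donor chromosome disappears, its centromere
    position is retained inside the splice, and n drops by one.
    """
    if donor_id == recipient_id:
        raise ValueError("donor and recipient must be different chromosomes")
    recipient = k[recipient_id]
    donor = k[donor_id]
    if not recipient.centromere_is_internal:
        raise ValueError(
            f"recipient {recipient_id} has a terminal centromere; "
            "nested insertion requires an internal one"
        )
    if donor_orientation == "forward":
        donor_blocks = donor.blocks
        donor_cent = donor.centromere
    elif donor_orientation == "inverted":
        donor_blocks = tuple(b.flipped() for b in reversed(donor.blocks))
        donor_cent = len(donor.blocks) - donor.centromere
    else:
        raise ValueError(f"donor_orientation must be forward or inverted, got {donor_orientation!r}")
    cut = recipient.centromere
    fused = ChromosomeModel(
        id=recipient.id,
        blocks=recipient.blocks[:cut] + donor_blocks + recipient.blocks[cut:],
        centromere=cut + donor_cent,
    )
    chroms = tuple(
        fused if c.id == recipient_id else c
        for c in k.chromosomes
        if c.id != donor_id
    )
    return Karyotype(chromosomes=chroms)


def invert_segment(
    chrom: ChromosomeModel,
    from_index: int,
    to_index: int,
    paracentric: bool = False,
) -> ChromosomeModel:
    """Reverse blocks from_index..to_index (inclusive) and flip their signs.

    With ``paracentric=True`` the segment must not span the centromere.
    """
    n = len(chrom.blocks)
    if not (0 <= from_index <= to_index < n):
        raise ValueError(
            f"invalid segment [{from_index}, {to_index}] for {n} blocks"
        )
    if paracentric and from_index < chrom.centromere <= to_index:
        raise ValueError(
            "paracentric inversion cannot span the centromere "
            f"(centromere at {chrom.centromere})"
        )
    seg = tuple(b.flipped() for b in reversed(chrom.blocks[from_index : to_index + 1]))
    return replace(
        chrom,
        blocks=chrom.blocks[:from_index] + seg + chrom.blocks[to_index + 1 :],
    )


# ---------------------------------------------------------------------------
# analysis

def block_copy_numbers(k: Karyotype) -> dict[str, float]:
    """Copy count per canonical block, with W's halves combined.

    A bare W counts as one full copy; Wa/Wb count half each, so a karyotype
    carrying Wa and Wb once each holds one full copy of W.
    """
    counts: dict[str, float] = {}
    for c in k.chromosomes:
        for b in c.blocks:
            if b.label in _SUBBLOCK_LABELS and b.sub is not None:
                counts[b.label] = counts.get(b.label, 0.0) + 0.5
            else:
                counts[b.label] = counts.get(b.label, 0.0) + 1.0
    return counts


def ploidy_call(k: Karyotype) -> str:
    """'tetraploid-origin' when every present block is at copy number 2."""
    counts = block_copy_numbers(k)
    if counts and all(v == 2 for v in counts.values()):
        return "tetraploid-origin"
    return "other"


def _strip_suffix(chrom_id: str) -> str:
    return re.sub(r"_\d+$", "", chrom_id)


@dataclass
class AncestralMatch:
    classifications: dict[str, str]  # chromosome id -> shared | derived
    matches: dict[str, str]  # shared chromosome id -> ancestral id
    events: list[KaryotypeEvent]

    @property
    def n_shared(self) -> int:
        return sum(1 for v in self.classifications.values() if v == "shared")

    @property
    def n_derived(self) -> int:
        return sum(1 for v in self.classifications.values() if v == "derived")


def match_ancestral(k: Karyotype, ancestral: Karyotype) -> AncestralMatch:
    """Classify chromosomes against an ancestral karyotype and detect NCIs.

    A chromosome is shared when its block content (order- and orientation-
    insensitive; Wa/Wb match their own half) equals that of some ancestral
    chromosome.  A derived chromosome carries an NCI signature when the
    full content of one ancestral chromosome (the donor) occurs as a
    contiguous, strictly internal run, flanked on both sides by blocks that
    together make up a second ancestral chromosome (the recipient).
    """
    anc_contents = {c.id: c.content for c in ancestral.chromosomes}
    classifications: dict[str, str] = {}
    matches: dict[str, str] = {}
    events: list[KaryotypeEvent] = []
    for c in k.chromosomes:
        content = c.content
        shared_with = next(
            (aid for aid, ac in anc_contents.items() if ac == content), None
        )
        if shared_with is not None:
            classifications[c.id] = "shared"
            matches[c.id] = shared_with
            continue
        classifications[c.id] = "derived"
        nci = _detect_nci(c, anc_contents)
        if nci is not None:
            donor, recipient = nci
            events.append(
                KaryotypeEvent(
                    kind="NCI",
                    participants=(donor, recipient),
                    inferred=True,
                    detail={
                        "fused_chromosome": c.id,
                        "donor": donor,
                        "recipient": recipient,
                    },
                )
            )
    return AncestralMatch(
        classifications=classifications, matches=matches, events=events
    )


def _detect_nci(
    chrom: ChromosomeModel, anc_contents: dict[str, Counter]
) -> tuple[str, str] | None:
    """Find (donor, recipient) ancestral ids for an NCI signature, if any."""
    keys = [b.content_key for b in chrom.blocks]
    n = len(keys)
    for start in range(1, n):  # strictly internal: non-empty prefix
        for end in range(start + 1, n):  # and non-empty suffix
            run = Counter(keys[start:end])
            flanks = Counter(keys[:start]) + Counter(keys[end:])
            donor = next(
                (aid for aid, ac in anc_contents.items() if ac == run), None
            )
            if donor is None:
                continue
            recipient = next(
                (aid for aid, ac in anc_contents.items() if ac == flanks), None
            )
            if recipient is not None:
                return donor, recipient
    return None


# ---------------------------------------------------------------------------
# presets

PRESETS: dict[str, str] = {
    # 8-chromosome ancestral Cardamineae karyotype; arm compositions follow
    # the published block assignments, centromeres between the two arms.
    "ACK_Cardamineae_n8": """\
# Ancestral Cardamineae karyotype, n = 8
AK1: A B | C .
AK2: D | E .
AK3: F G | H .
AK4: I | J .
AK5: K-L | M-N .
AK6/8: V Wa | Q R .
AK7: S T | U .
AK8/6: O P | Wb X .
""",
    # Reconstructed R. aquatica haploid complement (n = 15): six homeologous
    # pairs, the two unfused AK2/AK8-6 homeologues, and the RaChr15 fusion
    # chromosome formed by nested insertion of an inverted AK2 homeologue
    # into the AK8/6 centromere.
    "R_aquatica_n15": """\
# Reconstructed R. aquatica karyotype, n = 15
RaChr01: A B | C .
RaChr02: A B | C .
RaChr03: D | E .
RaChr04: F G | H .
RaChr05: F G | H .
RaChr06: I | J .
RaChr07: I | J .
RaChr08: K-L | M-N .
RaChr09: K-L | M-N .
RaChr10: V Wa | Q R .
RaChr11: V Wa | Q R .
RaChr12: S T | U .
RaChr13: S T | U .
RaChr14: O P | Wb X .
RaChr15: O P -E | -D Wb X .
""",
}


def load_preset(name: str) -> Karyotype:
    if name not in PRESETS:
        raise KeyError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}"
        )
    return parse_karyotype(PRESETS[name])
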