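"""Low-level DNA/peptide helpers shared across the package.

Everything here works on plain ``str`` sequences in uppercase ACGT.
Coordinates are 0-based, half-open throughout the package; conversion to
1-based inclusive happens only at AIRR export time.
"""

from __future__ import annotations

import random
import re

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# Standard genetic code; '*' marks stop codons.
_BASES = "TCAG"
_AA = (
    "FFLLSSSSYY**CC*W"
    "LLLLPPPPHHQQRRRR"
    "IIIMTTTTNNKKSSRR"
    "VVVVAAAADDEEGGGG"
)
CODON_TABLE = {
    a + b + c: _AA[16 * i + 4 * j + k]
    for i, a in enumerate(_BASES)
    for j, b in enumerate(_BASES)
    for k, c in enumerate(_BASES)
}
SENSE_CODONS = sorted(c for c, aa in CODON_TABLE.items() if aa != "*")
STOP_CODONS = ("TAA", "TAG", "TGA")

#: cryptic RSS heptamer near the 3' end of most V segments
CRSS = "TACTGTG"
#: conventional RSS heptamer with the degenerate fifth position
RSS_HEPTAMER_RE = re.compile("CACA[GAT]TG")
#: either motif; used to scrub synthetic background sequence
ANY_MOTIF_RE = re.compile("TACTGTG|CACA[GAT]TG")

_DNA_RE = re.compile("^[ACGT]+$")


def require_dna(seq: str) -> str:
    """Raise ``ValueError`` unless *seq* is non-empty uppercase ACGT."""
    if not seq or not _DNA_RE.match(seq):
        raise ValueError(f"not a plain ACGT sequence: {seq[:40]!r}...")
    return seq


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def translate(seq: str) -> str:
    """Translate *seq* from position 0; trailing partial codon is dropped."""
    table = CODON_TABLE
    return "".join(
        table.get(seq[i : i + 3], "X") for i in range(0, len(seq) - 2, 3)
    )


def hamming(a: str, b: str) -> int:
    """Mismatch count between equal-length strings."""
    if len(a) != len(b):
        raise ValueError("hamming() needs equal-length sequences")
    return sum(x != y for x, y in zip(a, b))


def hamming_at_most(a: str, b: str, limit: int) -> int | None:
    """Mismatches between equal-length strings, or None once > limit."""
    mm = 0
    for x, y in zip(a, b):
        if x != y:
            mm += 1
            if mm > limit:
                return None
    return mm


def random_dna(rng: random.Random, n: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(n))


def scrub_motifs(seq: str, rng: random.Random, max_rounds: int = 50) -> str:
    """Mutate *seq* until it contains neither RSS motif.

    Used when generating synthetic background sequence that must be free of
    the cRSS/RSS heptamers so that planted signal joints are the only
    junction strings in a library.
    """
    s = list(seq)
    for _ in range(max_rounds):
        m = ANY_MOTIF_RE.search("".join(s))
        if m is None:
            return "".join(s)
        pos = m.start() + 3
        s[pos] = rng.choice([b for b in "ACGT" if b != s[pos]])
    raise RuntimeError("could not scrub motifs from sequence")


def random_sense_codons(rng: random.Random, n: int) -> str:
    """n random non-stop codons (an open reading frame fragment)."""
    return "".join(rng.choice(SENSE_CODONS) for _ in range(n))


def scrub_motifs_in_frame(seq: str, rng: random.Random, lock: tuple[int, int] = (0, 0)) -> str:
    """Remove RSS motifs from an ORF by resampling whole codons.

    ``lock`` is a half-open nt interval that must not be touched (e.g. a
    deliberately planted cRSS).  The returned sequence stays stop-free in
    frame 0 wherever codons were replaced.
    """
    s = seq
    for _ in range(100):
        hit = None
        for m in ANY_MOTIF_RE.finditer(s):
            if lock[0] <= m.start() and m.end() <= lock[1]:
                continue
            hit = m
            break
        if hit is None:
            return s
        # replace the codon containing the middle of the motif
        codon_i = (hit.start() + 3) // 3
        if lock[0] // 3 <= codon_i < (lock[1] + 2) // 3:
            codon_i = hit.start() // 3  # fall back to the first codon
        new = rng.choice(SENSE_CODONS)
        s = s[: 3 * codon_i] + new + s[3 * codon_i + 3 :]
    raise RuntimeError("could not scrub motifs from ORF")
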