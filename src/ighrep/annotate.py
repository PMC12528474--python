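"""Read processing and AIRR-style rearrangement annotation.

The pipeline is the usual one for UMI-tagged amplicon repertoire data:
merge read pairs by best ungapped overlap, collapse PCR duplicates on the
(UMI, sequence length) key, then annotate each molecule against the germline
locus: V and J by anchored ungapped matching, D by the best >=6-nt exact
match inside the junction, productivity from the V->J reading frame and an
in-frame stop scan bounded by the conserved J tryptophan, CDR3 between the
invariant Cys96 and that tryptophan, and the D reading frame in the
Ichihara numbering (the convention in which RF2 carries the Dmu ATG and RF3
the frequent stops).

Internal coordinates are 0-based half-open; AIRR export is 1-based.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .locus_model import CYS_NT, GermlineLocus
from .seqtools import hamming_at_most, revcomp, translate

UMI_RE = re.compile(r"UMI:([ACGT]{8,})")

# V anchor: 40 nt ending at the cRSS position -- 5' of the trim zone, so it
# is present in every V remnant.  J anchor: 30 nt starting past the maximum
# 5' trim.
V_ANCHOR_START, V_ANCHOR_END = 242, 282
J_ANCHOR_START = 15
J_ANCHOR_LEN = 30


@dataclass
class Molecule:
    molecule_id: str
    umi: str
    sequence: str
    duplicate_count: int
    mean_quality: float = 0.0


@dataclass
class CDR3Record:
    residues: str
    start_pos: int = 97

    @property
    def length_aa(self) -> int:
        return len(self.residues)

    @property
    def pos_map(self) -> dict[int, str]:
        return {self.start_pos + i: aa for i, aa in enumerate(self.residues)}


# --- UMI deduplication ---------------------------------------------------

def dedup_by_umi(reads):
    """Collapse reads to molecules on the (UMI, sequence length) key.

    *reads* is an iterable of (read_id, sequence, quality) triples; the
    representative is the read with the highest mean quality, ties broken by
    lexicographic sequence.  Reads without a parsable UMI token go to an
    'unparsed' sink and are counted.

    Returns (molecules, sink_counts).
    """
    groups: dict[tuple[str, int], list] = {}
    sink = {"unparsed": 0}
    for read_id, seq, qual in reads:
        m = UMI_RE.search(read_id)
        if m is None:
            sink["unparsed"] += 1
            continue
        umi = m.group(1)
        mq = (sum(qual) / len(qual)) if isinstance(qual, (list, tuple)) else (
            sum(ord(c) - 33 for c in qual) / len(qual) if qual else 0.0)
        groups.setdefault((umi, len(seq)), []).append((read_id, seq, mq))
    molecules = []
    for i, ((umi, _), members) in enumerate(sorted(groups.items())):
        members.sort(key=lambda r: (-r[2], r[1]))
        rid, seq, mq = members[0]
        molecules.append(Molecule(molecule_id=rid.split("_UMI")[0], umi=umi,
                                  sequence=seq, duplicate_count=len(members),
                                  mean_quality=mq))
    return molecules, sink


# --- pair merging --------------------------------------------------------

def merge_pairs(r1: str, r2: str, min_overlap: int = 20,
                max_mismatch_frac: float = 0.1) -> str | None:
    """Merge mates by the best ungapped overlap of r1's 3' end with the
    reverse complement of r2; returns the consensus (r1 orientation) or
    None when no acceptable overlap exists."""
    b = revcomp(r2)
    best = None
    for ov in range(min(len(r1), len(b)), min_overlap - 1, -1):
        tail, head = r1[-ov:], b[:ov]
        if tail == head:
            best = (0, ov)
            break
        limit = int(max_mismatch_frac * ov)
        mm = hamming_at_most(tail, head, limit)
        if mm is not None and (best is None or mm / ov < best[0] / best[1]):
            best = (mm, ov)
            if mm == 0:
                break
    if best is None:
        return None
    _, ov = best
    return r1 + b[ov:]


# --- segment assignment --------------------------------------------------

def _find_anchor(seq: str, anchor: str, max_mm: int) -> tuple[int, int] | None:
    """Locate *anchor* in *seq* allowing up to max_mm substitutions.

    Fast path: exact find of the whole anchor, then exact find of either
    half with a verification of the implied full window.  Returns
    (position, mismatches) or None.
    """
    pos = seq.find(anchor)
    if pos != -1:
        return pos, 0
    half = len(anchor) // 2
    for part, shift in ((anchor[:half], 0), (anchor[half:], half)):
        start = 0
        while True:
            p = seq.find(part, start)
            if p == -1:
                break
            w0 = p - shift
            if 0 <= w0 <= len(seq) - len(anchor):
                mm = hamming_at_most(seq[w0 : w0 + len(anchor)], anchor, max_mm)
                if mm is not None:
                    return w0, mm
            start = p + 1
    return None


@dataclass
class Row:
    """One annotated molecule (AIRR-style rearrangement row)."""

    sequence_id: str
    sequence: str
    umi: str = ""
    duplicate_count: int = 1
    v_call: str | None = None
    d_call: str | None = None
    j_call: str | None = None
    junction_nt: str | None = None
    junction_aa: str | None = None
    cdr3_aa: str | None = None
    productive: bool | None = None
    d_rf: int | None = None
    stop_codon: bool = False
    frame_shift: int | None = None
    stage: str = ""
    ambiguous_v: bool = False
    flags: list = field(default_factory=list)
    # internal coordinates (0-based, on `sequence`)
    _frame_anchor: int | None = None
    _j_start: int | None = None
    _d_pos: int | None = None
    _d_offset: int | None = None


def assign_segments(seq: str, locus: GermlineLocus, min_seed: int = 20,
                    max_mm: int = 2) -> Row | None:
    """Assign V/D/J by anchored ungapped matching.

    No J match -> None (the capture is J-anchored, so the read is discarded
    to the sink).  No V match -> DJ-only row.  Tied best V scores take the
    lower locus rank and set the ambiguity flag.
    """
    best_j = None
    for j in locus.j_segments:
        anchor = j.seq[J_ANCHOR_START : J_ANCHOR_START + J_ANCHOR_LEN]
        if len(anchor) < min_seed:
            anchor = j.seq[J_ANCHOR_START:]
        hit = _find_anchor(seq, anchor, max_mm)
        if hit and (best_j is None or hit[1] < best_j[2]):
            best_j = (j, hit[0], hit[1])
    if best_j is None:
        return None
    j, j_anchor_pos, _ = best_j
    j_start = j_anchor_pos - J_ANCHOR_START

    best_v = None  # (v, pos, mm); v_segments iterate proximal-first, so the
    tie = False    # lower locus_rank wins ties deterministically
    for v in locus.v_segments:
        anchor = v.coding_seq[V_ANCHOR_START:V_ANCHOR_END]
        hit = _find_anchor(seq[: max(0, j_start)], anchor, max_mm)
        if hit is None:
            continue
        if best_v is None or hit[1] < best_v[2]:
            best_v = (v, hit[0], hit[1])
            tie = False
        elif hit[1] == best_v[2]:
            tie = True

    row = Row(sequence_id="", sequence=seq, j_call=j.name, _j_start=j_start)
    if best_v is not None:
        v, v_pos, _ = best_v
        row.v_call = v.name
        row.ambiguous_v = tie
        row._frame_anchor = v_pos - V_ANCHOR_START

    # D: best exact match of >= 6 nt inside the junction window
    lo = (row._frame_anchor + V_ANCHOR_END) if row._frame_anchor is not None else 0
    hi = max(lo, j_start + J_ANCHOR_START)
    window = seq[lo:hi]
    best_d = None
    for d in locus.d_segments:
        for off in range(len(d.seq) - 5):
            p = window.find(d.seq[off : off + 6])
            if p == -1:
                continue
            # extend the exact match to the right
            length = 6
            while (off + length < len(d.seq) and p + length < len(window)
                   and d.seq[off + length] == window[p + length]):
                length += 1
            if best_d is None or length > best_d[3]:
                best_d = (d, lo + p, off, length)
    if best_d is not None:
        d, pos, off, length = best_d
        row.d_call = d.name
        row._d_pos, row._d_offset = pos, off
    row.junction_nt = seq[lo:hi]
    return row


# --- productivity, CDR3, D reading frame ---------------------------------

def call_productivity(row: Row, locus: GermlineLocus) -> Row:
    """Frame shift, bounded stop scan and the productive flag."""
    if row.v_call is None or row.j_call is None:
        row.productive = None
        return row
    j = locus.j_by_name[row.j_call]
    fa, js = row._frame_anchor, row._j_start
    row.frame_shift = (js + j.frame_offset - fa) % 3
    w_pos = js + j.trp_offset
    cys_pos = fa + CYS_NT
    start = cys_pos if cys_pos >= 0 else fa % 3
    end = w_pos + 3
    if row.sequence[w_pos : w_pos + 3] != "TGG":
        end = min(len(row.sequence), js + len(j.seq))  # degraded W: scan to junction end
        row.flags.append("no_conserved_w")
    seg = row.sequence[start:end]
    row.stop_codon = "*" in translate(seg)
    row.productive = row.frame_shift == 0 and not row.stop_codon
    row.junction_nt = row.sequence[cys_pos : w_pos + 3] if cys_pos >= 0 else None
    if row.productive and row.junction_nt and len(row.junction_nt) % 3 == 0:
        row.junction_aa = translate(row.junction_nt)
    return row


def extract_cdr3(row: Row, locus: GermlineLocus) -> CDR3Record | None:
    """CDR3 between the invariant Cys96 and the conserved J tryptophan;
    None when out of frame or either landmark is missing."""
    if row.v_call is None or row.j_call is None or row.frame_shift != 0:
        return None
    j = locus.j_by_name[row.j_call]
    cys_pos = row._frame_anchor + CYS_NT
    w_pos = row._j_start + j.trp_offset
    if cys_pos < 0 or row.sequence[cys_pos : cys_pos + 3] not in ("TGT", "TGC"):
        return None
    if row.sequence[w_pos : w_pos + 3] != "TGG":
        return None
    residues = translate(row.sequence[cys_pos + 3 : w_pos])
    row.cdr3_aa = residues
    return CDR3Record(residues=residues)


def assign_d_rf(row: Row, locus: GermlineLocus) -> int | None:
    """Ichihara reading frame of the matched D in the translation frame."""
    if row.d_call is None or row._frame_anchor is None or row._d_pos is None:
        return None
    r = (row._d_offset + row._frame_anchor - row._d_pos) % 3
    row.d_rf = r + 1
    return row.d_rf


def transpose_rf_imgt_to_ichihara(rf: int) -> int:
    """IMGT D reading-frame id to Ichihara id: 1->2, 2->3, 3->1."""
    if rf not in (1, 2, 3):
        raise ValueError("reading frame must be 1, 2 or 3")
    return rf % 3 + 1


# --- whole-molecule driver and AIRR IO -----------------------------------

def annotate_molecules(molecules, locus: GermlineLocus, min_seed: int = 20,
                       max_mm: int = 2, stage: str = ""):
    """Annotate deduplicated molecules; returns (DataFrame, sink_counts)."""
    rows = []
    sink = {"no_j": 0}
    for mol in molecules:
        row = assign_segments(mol.sequence, locus, min_seed=min_seed, max_mm=max_mm)
        if row is None:
            sink["no_j"] += 1
            continue
        row.sequence_id = mol.molecule_id
        row.umi = mol.umi
        row.duplicate_count = mol.duplicate_count
        row.stage = stage
        call_productivity(row, locus)
        extract_cdr3(row, locus)
        assign_d_rf(row, locus)
        rows.append(row)
    return rows_to_frame(rows), sink


def rows_to_frame(rows) -> pd.DataFrame:
    recs = []
    for r in rows:
        recs.append(dict(
            sequence_id=r.sequence_id, sequence=r.sequence, umi=r.umi,
            v_call=r.v_call, d_call=r.d_call, j_call=r.j_call,
            junction=r.junction_nt, junction_aa=r.junction_aa,
            cdr3_aa=r.cdr3_aa, productive=r.productive,
            stop_codon=r.stop_codon, frame_shift=r.frame_shift,
            duplicate_count=r.duplicate_count, d_rf=r.d_rf, stage=r.stage,
            ambiguous_v=r.ambiguous_v, flags=";".join(r.flags),
        ))
    return pd.DataFrame(recs)


AIRR_COLUMNS = ["sequence_id", "sequence", "v_call", "d_call", "j_call",
                "junction", "junction_aa", "productive", "stop_codon",
                "duplicate_count", "d_rf", "stage", "cdr3_aa", "frame_shift",
                "umi", "ambiguous_v", "flags"]


def write_airr_tsv(frame: pd.DataFrame, path: str | Path) -> None:
    out = frame.copy()
    for col in AIRR_COLUMNS:
        if col not in out.columns:
            out[col] = None
    out[AIRR_COLUMNS].to_csv(path, sep="\t", index=False)


def read_airr_tsv(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t")
    for col in ("productive", "stop_codon"):
        if col in frame.columns and frame[col].dtype == object:
            frame[col] = frame[col].map({"True": True, "False": False, True: True, False: False})
    return frame
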