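"""VH-replacement excision-circle detection in FR3 run-off libraries.

A replacement circle carries the replaced (recipient) V ending in its
cryptic RSS heptamer ``TACTGTG``, a 0-4 nt insertion, the invading (donor)
V's conventional heptamer ``CACA[GAT]TG`` back-to-back, and the donor's 3'
intergenic sequence.  Detection runs in two passes:

* the main search anchors 60 nt of recipient framework-3, allows a variable
  gap containing the back-to-back heptamers, and requires 60 nt of a
  different V's 3' intergenic sequence downstream;
* a grep-style fallback looks only for the back-to-back heptamer string
  (insertions up to 3 nt) and is curated with shorter (>=20 nt) anchors,
  rescuing molecules too short for the full donor anchor.

Automated curation applies the checks a manual curator would: junction
pattern present, both anchors solid, donor distinct from and locus-distal
to the recipient.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import pandas as pd

from .locus_model import GermlineLocus
from .seqtools import CRSS, hamming_at_most

JUNCTION_RE = re.compile(r"TACTGTG([ACGT]{0,4}?)(CACA[GAT]TG)")
FALLBACK_RE_TEMPLATE = r"TACTGTG([ACGT]{{0,{max_ins}}}?)(CACA[GAT]TG)"

REJECT_NO_JUNCTION = "no_junction"
REJECT_WEAK_ANCHOR = "weak_anchor"
REJECT_SELF_MATCH = "self_match"
REJECT_NOT_DISTAL = "donor_not_distal"
REJECT_UNKNOWN_V = "unknown_v"


@dataclass
class CircleCandidate:
    read_id: str
    sequence: str
    junction_pos: int          # start of TACTGTG
    insertion_nt: str
    heptamer: str
    recipient_v: str | None
    donor_v: str | None
    recipient_match_len: int
    recipient_mm: int
    donor_match_len: int
    donor_mm: int
    source: str                # 'main' | 'fallback'


@dataclass
class ReplacementCircleCall:
    read_id: str
    recipient_v: str
    donor_v: str
    insertion_nt: str
    junction_string: str
    recipient_match_len: int
    donor_match_len: int
    source: str
    curated: bool
    reject_reason: str | None = None


def _best_window_match(seq: str, anchor: str, lo: int, hi: int,
                       max_mm: int) -> tuple[int, int] | None:
    """Best (pos, mm) placement of *anchor* fully inside seq[lo:hi]."""
    best = None
    pos = seq.find(anchor, lo, hi)
    if pos != -1 and pos + len(anchor) <= hi:
        return pos, 0
    for p in range(lo, hi - len(anchor) + 1):
        mm = hamming_at_most(seq[p : p + len(anchor)], anchor, max_mm)
        if mm is not None and (best is None or mm < best[1]):
            best = (p, mm)
            if mm == 0:
                break
    return best


def _junction_sites(seq: str, max_ins: int):
    """All (crss_pos, insertion, heptamer, heptamer_end) junction strings."""
    sites = []
    start = 0
    while True:
        p = seq.find(CRSS, start)
        if p == -1:
            break
        for ins_len in range(0, max_ins + 1):
            h0 = p + 7 + ins_len
            hept = seq[h0 : h0 + 7]
            if len(hept) == 7 and hept.startswith("CACA") and hept[4] in "GAT" \
                    and hept.endswith("TG"):
                sites.append((p, seq[p + 7 : h0], hept, h0 + 7))
        start = p + 1
    return sites


def find_circles_main(molecules, locus: GermlineLocus, anchor_len: int = 60,
                      max_mm: int = 2, gap_range=(10, 120),
                      insertion_range=(0, 4)) -> list[CircleCandidate]:
    """Anchored search: best recipient by FR3 match upstream of a junction
    string, best distinct donor by intergenic match downstream, at most one
    candidate (the best-scoring junction) per molecule.  Molecules without
    both anchors are skipped silently."""
    out = []
    vs = [v for v in locus.v_segments]
    for mol in molecules:
        seq = mol.sequence
        best = None
        for crss_pos, ins, hept, h_end in _junction_sites(seq, insertion_range[1]):
            # recipient: FR3 anchor in a window upstream of the cRSS
            rec_hit = None
            lo = max(0, crss_pos - gap_range[1] - anchor_len)
            for v in vs:
                anchor = v.fr3_seq[-anchor_len:]
                if len(anchor) < anchor_len:
                    continue
                hit = _best_window_match(seq, anchor, lo, crss_pos, max_mm)
                if hit is None:
                    continue
                gap = h_end - (hit[0] + anchor_len)
                if not gap_range[0] <= gap <= gap_range[1]:
                    continue
                if rec_hit is None or hit[1] < rec_hit[2]:
                    rec_hit = (v, hit[0], hit[1])
            if rec_hit is None:
                continue
            don_hit = None
            for v in vs:
                if v.name == rec_hit[0].name:
                    continue
                anchor = v.intergenic_3p[:anchor_len]
                window = seq[h_end : h_end + anchor_len]
                if len(window) < anchor_len:
                    continue
                mm = hamming_at_most(window, anchor, max_mm)
                if mm is not None and (don_hit is None or mm < don_hit[1]):
                    don_hit = (v, mm)
            if don_hit is None:
                continue
            score = rec_hit[2] + don_hit[1]
            if best is None or score < best[0]:
                best = (score, CircleCandidate(
                    read_id=mol.molecule_id, sequence=seq, junction_pos=crss_pos,
                    insertion_nt=ins, heptamer=hept,
                    recipient_v=rec_hit[0].name, donor_v=don_hit[0].name,
                    recipient_match_len=anchor_len, recipient_mm=rec_hit[2],
                    donor_match_len=anchor_len, donor_mm=don_hit[1],
                    source="main"))
        if best is not None:
            out.append(best[1])
    return out


def find_circles_fallback(molecules, locus: GermlineLocus, insertion_max: int = 3,
                          anchor_len: int = 20, max_mm: int = 1) -> list[CircleCandidate]:
    """Direct back-to-back heptamer search (grep-style), with reduced-length
    anchor identification for reads too short for the 60-nt donor anchor."""
    out = []
    for mol in molecules:
        seq = mol.sequence
        for crss_pos, ins, hept, h_end in _junction_sites(seq, insertion_max):
            rec_hit = None
            if crss_pos >= anchor_len:
                window = seq[crss_pos - anchor_len : crss_pos]
                for v in locus.v_segments:
                    if v.crss_offset is None:
                        continue
                    anchor = v.coding_seq[v.crss_offset - anchor_len : v.crss_offset]
                    mm = hamming_at_most(window, anchor, max_mm)
                    if mm is not None and (rec_hit is None or mm < rec_hit[1]):
                        rec_hit = (v, mm)
            don_hit = None
            window = seq[h_end : h_end + anchor_len]
            if len(window) == anchor_len:
                for v in locus.v_segments:
                    mm = hamming_at_most(window, v.intergenic_3p[:anchor_len], max_mm)
                    if mm is not None and (don_hit is None or mm < don_hit[1]):
                        don_hit = (v, mm)
            out.append(CircleCandidate(
                read_id=mol.molecule_id, sequence=seq, junction_pos=crss_pos,
                insertion_nt=ins, heptamer=hept,
                recipient_v=rec_hit[0].name if rec_hit else None,
                donor_v=don_hit[0].name if don_hit else None,
                recipient_match_len=anchor_len if rec_hit else 0,
                recipient_mm=rec_hit[1] if rec_hit else 0,
                donor_match_len=anchor_len if don_hit else 0,
                donor_mm=don_hit[1] if don_hit else 0,
                source="fallback"))
            break  # one candidate per molecule
    return out


def curate_call(candidate: CircleCandidate, locus: GermlineLocus,
                min_anchor: int = 20, max_mm_frac: float = 0.034) -> ReplacementCircleCall:
    """Apply the curation checks: junction pattern, anchor strength, donor
    distinct from and distal to the recipient."""
    junction = candidate.sequence[candidate.junction_pos :
                                  candidate.junction_pos + 14 + len(candidate.insertion_nt)]
    call = ReplacementCircleCall(
        read_id=candidate.read_id,
        recipient_v=candidate.recipient_v or "",
        donor_v=candidate.donor_v or "",
        insertion_nt=candidate.insertion_nt,
        junction_string=junction,
        recipient_match_len=candidate.recipient_match_len,
        donor_match_len=candidate.donor_match_len,
        source=candidate.source,
        curated=False,
    )
    if not JUNCTION_RE.match(junction):
        call.reject_reason = REJECT_NO_JUNCTION
        return call
    if candidate.recipient_v is None or candidate.donor_v is None:
        call.reject_reason = REJECT_WEAK_ANCHOR
        return call
    v_by_name = locus.v_by_name
    if candidate.recipient_v not in v_by_name or candidate.donor_v not in v_by_name:
        call.reject_reason = REJECT_UNKNOWN_V
        return call
    for length, mm in ((candidate.recipient_match_len, candidate.recipient_mm),
                       (candidate.donor_match_len, candidate.donor_mm)):
        if length < min_anchor or mm > max_mm_frac * length:
            call.reject_reason = REJECT_WEAK_ANCHOR
            return call
    if candidate.recipient_v == candidate.donor_v:
        call.reject_reason = REJECT_SELF_MATCH
        return call
    if v_by_name[candidate.donor_v].locus_rank <= v_by_name[candidate.recipient_v].locus_rank:
        call.reject_reason = REJECT_NOT_DISTAL
        return call
    call.curated = True
    return call


def detect_circles(molecules, locus: GermlineLocus, **main_kwargs):
    """Main search, then fallback on molecules the main search missed;
    curation on everything.  Returns the full call list (curated flag set)."""
    main = find_circles_main(molecules, locus, **main_kwargs)
    seen = {c.read_id for c in main}
    rest = [m for m in molecules if m.molecule_id not in seen]
    fallback = find_circles_fallback(rest, locus)
    calls = [curate_call(c, locus) for c in main + fallback]
    for call in calls:
        if call.curated:
            assert (locus.v_by_name[call.donor_v].locus_rank
                    > locus.v_by_name[call.recipient_v].locus_rank)
    return calls


def summarize_circles(calls, locus: GermlineLocus,
                      library_of: dict | None = None) -> dict:
    """Donor/recipient locus-position maps, insertion-length histogram and
    per-library counts for curated calls."""
    curated = [c for c in calls if c.curated]
    ranks = {v.name: v.locus_rank for v in locus.v_segments}
    donor_map = pd.Series([c.donor_v for c in curated]).value_counts() \
        if curated else pd.Series(dtype=int)
    recipient_map = pd.Series([c.recipient_v for c in curated]).value_counts() \
        if curated else pd.Series(dtype=int)
    ins_hist = pd.Series([len(c.insertion_nt) for c in curated]).value_counts() \
        .reindex(range(0, 5), fill_value=0) if curated else \
        pd.Series(0, index=range(0, 5))
    per_library = {}
    if library_of:
        for c in curated:
            lib = library_of.get(c.read_id, "unknown")
            per_library[lib] = per_library.get(lib, 0) + 1
    return dict(
        donor_map=donor_map, recipient_map=recipient_map,
        donor_ranks=donor_map.rename(index=ranks) if len(donor_map) else donor_map,
        recipient_ranks=recipient_map.rename(index=ranks) if len(recipient_map) else recipient_map,
        insertion_hist=ins_hist, per_library=per_library,
        n_curated=len(curated), n_candidates=len(calls),
    )


def library_ratio(count_a: int, counts_b) -> float | None:
    """Ratio statistic count_a / mean(counts_b); None when undefined."""
    counts_b = list(counts_b)
    if not counts_b or sum(counts_b) == 0:
        return None
    return count_a / (sum(counts_b) / len(counts_b))


CALL_COLUMNS = ["read_id", "recipient_v", "donor_v", "insertion_nt",
                "insertion_len", "junction_string", "recipient_match_len",
                "donor_match_len", "source", "curated", "reject_reason"]


def calls_to_frame(calls) -> pd.DataFrame:
    if not calls:
        return pd.DataFrame(columns=CALL_COLUMNS)
    return pd.DataFrame([
        dict(read_id=c.read_id, recipient_v=c.recipient_v, donor_v=c.donor_v,
             insertion_nt=c.insertion_nt, insertion_len=len(c.insertion_nt),
             junction_string=c.junction_string,
             recipient_match_len=c.recipient_match_len,
             donor_match_len=c.donor_match_len, source=c.source,
             curated=c.curated, reject_reason=c.reject_reason)
        for c in calls
    ])
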