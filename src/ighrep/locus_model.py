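"""Germline heavy-chain locus representation and deterministic toy loci.

The package models a simplified IgH locus: an ordered array of V segments
(proximal to distal, ``locus_rank`` 1 = most D-proximal), a handful of D
segments in forward orientation only, and J segments carrying the conserved
tryptophan.  Segment sequences are synthetic but structurally faithful:

* each V coding sequence is a stop-free open reading frame with the
  invariant Cys at residue 96 (codon 95, 0-based nt 285) and, for most V,
  the cryptic RSS heptamer ``TACTGTG`` overlapping the Tyr95/Cys96 codons a
  few bases from the 3' end — exactly the geometry that makes VH-replacement
  possible;
* each V carries a conventional RSS heptamer (``CACA[GAT]TG``) and a unique
  3' intergenic sequence, which together form the donor-side signature of a
  replacement excision circle;
* D segments are short and carry the hallmark reading-frame structure: an
  ATG in reading frame 2 (the Dmu frame) and, for at least one D, a stop
  codon in reading frame 3;
* J segments differ in how many codons they contribute to the CDR3 (JH2/JH3
  two residues fewer than JH1/JH4).

All synthetic background sequence is scrubbed of both RSS motifs so planted
signal joints are the only junction strings present in simulated libraries.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .seqtools import (
    ANY_MOTIF_RE,
    CRSS,
    require_dna,
    random_dna,
    random_sense_codons,
    scrub_motifs,
    scrub_motifs_in_frame,
    translate,
)

# --- fixed geometry of toy V segments -----------------------------------
V_LEN = 294          # nt; 98 codons, frame 0 anchored at position 0
CRSS_NT = 282        # cRSS start: TAC TGT G spans Tyr95/Cys96
CYS_NT = 285         # codon of the invariant Cys96
FR3_START, FR3_END = 222, 282   # 60-nt framework-3 window used as anchor
CRSS_WINDOW = 30     # "a few basepairs from 3'" operationalised as 30 nt

UNKNOWN_CLAN = "unknown"


@dataclass
class VSegment:
    name: str
    locus_rank: int
    family: str
    clan: int | str
    coding_seq: str
    fr3_seq: str
    rss_heptamer: str
    intergenic_3p: str
    crss_offset: int | None = None
    ends_ta: bool = False

    def __post_init__(self) -> None:
        if len(self.coding_seq) < 90 or len(self.coding_seq) % 3:
            raise ValueError(f"{self.name}: V coding_seq must be >=90 nt, multiple of 3")
        if self.crss_offset is not None:
            window = self.coding_seq[self.crss_offset : self.crss_offset + 7]
            if window != CRSS or self.crss_offset < len(self.coding_seq) - CRSS_WINDOW:
                raise ValueError(f"{self.name}: crss_offset does not locate {CRSS}")
        self.ends_ta = self.coding_seq.endswith("TA")


@dataclass
class DSegment:
    name: str
    seq: str
    rf_peptides: tuple[str, str, str] = field(init=False)
    rf_has_stop: tuple[bool, bool, bool] = field(init=False)
    rf2_has_atg: bool = field(init=False)

    def __post_init__(self) -> None:
        peps = tuple(translate(self.seq[i:]) for i in range(3))
        self.rf_peptides = peps
        self.rf_has_stop = tuple("*" in p for p in peps)
        self.rf2_has_atg = "M" in peps[1]


@dataclass
class JSegment:
    name: str
    seq: str
    frame_offset: int          # reading frame of the conserved Trp
    trp_offset: int            # nt offset of the conserved TGG
    cdr3_contribution_aa: int  # codons contributed to the CDR3 before the Trp

    def __post_init__(self) -> None:
        if self.seq[self.trp_offset : self.trp_offset + 3] != "TGG":
            raise ValueError(f"{self.name}: no TGG at trp_offset")
        if (self.trp_offset - self.frame_offset) % 3:
            raise ValueError(f"{self.name}: Trp not in frame_offset frame")


@dataclass
class GermlineLocus:
    name: str
    v_segments: list[VSegment]
    d_segments: list[DSegment]
    j_segments: list[JSegment]

    def __post_init__(self) -> None:
        if len(self.v_segments) < 2 or not self.d_segments or len(self.j_segments) < 2:
            raise ValueError("locus needs >=2 V, >=1 D, >=2 J")
        ranks = [v.locus_rank for v in self.v_segments]
        if len(set(ranks)) != len(ranks):
            raise ValueError("locus_rank values must be unique")

    @property
    def v_by_name(self) -> dict[str, VSegment]:
        return {v.name: v for v in self.v_segments}

    @property
    def j_by_name(self) -> dict[str, JSegment]:
        return {j.name: j for j in self.j_segments}

    @property
    def d_by_name(self) -> dict[str, DSegment]:
        return {d.name: d for d in self.d_segments}

    def clan_table(self) -> dict[str, int | str]:
        return {v.name: v.clan for v in self.v_segments}


# --- motif queries -------------------------------------------------------

def detect_crss(v_seq: str, window: int = CRSS_WINDOW) -> int | None:
    """0-based start of the 3'-most exact TACTGTG starting in the last
    *window* nt of *v_seq*, or None."""
    require_dna(v_seq)
    if len(v_seq) < window:
        raise ValueError(f"sequence shorter than the {window}-nt search window")
    lo = len(v_seq) - window
    pos = v_seq.rfind(CRSS)
    while pos != -1:
        if pos >= lo:
            return pos
        pos = v_seq.rfind(CRSS, 0, pos)
    return None


def ends_with_ta(v_seq: str) -> bool:
    """True iff the V segment ends with the first two bases of a stop codon."""
    require_dna(v_seq)
    if len(v_seq) < 2:
        raise ValueError("need at least 2 nt")
    return v_seq.endswith("TA")


def clan_of(v_name: str, clan_table: dict) -> int | str:
    """Clan lookup by gene name, falling back to the family prefix."""
    if v_name in clan_table:
        return clan_table[v_name]
    family = v_name.split("-")[0]
    return clan_table.get(family, UNKNOWN_CLAN)


def load_default_clan_table() -> dict:
    """Family-level clan assignments packaged as a config table."""
    from importlib import resources

    with resources.files("ighrep").joinpath("data/clans.yaml").open() as fh:
        return yaml.safe_load(fh)


# --- toy locus generator -------------------------------------------------

_FAMILY_PLAN = ["VH5", "VH2", "VH3", "VH6", "VH1", "VH14"]
# fraction of the V array given to each family (proximal -> distal)
_FAMILY_FRACTIONS = [0.14, 0.14, 0.14, 0.14, 0.37, 0.07]
# real-flavoured member numbering for the first few genes of a family
_FAMILY_NUMBERING = {
    "VH5": [2, 4, 6, 12],
    "VH2": [2, 3, 6, 9],
    "VH3": [1, 6, 8],
    "VH1": [11, 26, 81],
    "VH6": [3],
    "VH14": [1, 2],
}
_D_NAMES = ["DFL16.1", "DSP2.2", "DSP2.9", "DQ52"]


def _family_of_rank(rank: int, n_v: int) -> str:
    if n_v < 6:
        return _FAMILY_PLAN[(rank - 1) % 3]
    cum = 0.0
    for fam, frac in zip(_FAMILY_PLAN, _FAMILY_FRACTIONS):
        cum += frac
        if (rank - 1) / n_v < cum:
            return fam
    return _FAMILY_PLAN[-1]


def _make_d(rng: random.Random, want_rf3_stop: bool) -> str:
    """Search for a 17-mer D with the canonical reading-frame structure."""
    weights = "GGTTAC"  # G/T rich: RF1 tends to G/Y, RF2 to T/V
    for _ in range(100_000):
        seq = "".join(rng.choice(weights) for _ in range(17))
        peps = [translate(seq[i:]) for i in range(3)]
        if "*" in peps[0] or "*" in peps[1]:
            continue                       # RF1 usable, no stop in RF2
        if "M" not in peps[1]:
            continue                       # Dmu ATG in RF2
        if ("*" in peps[2]) != want_rf3_stop:
            continue
        if sum(peps[0].count(a) for a in "GYS") < 2:
            continue
        if sum(peps[1].count(a) for a in "TVI") < 2:
            continue
        if ANY_MOTIF_RE.search(seq):
            continue
        return seq
    raise RuntimeError("D segment search failed")


def _make_j(rng: random.Random, jh_index: int) -> JSegment:
    k = 6 if jh_index in (1, 4) else 4 if jh_index in (2, 3) else 6
    pool = ["TAT", "TAC", "GGT", "GCT", "TCT", "GAT"]
    head = [rng.choice(pool) for _ in range(k)]
    if jh_index in (1, 4):
        head[0], head[1] = "TAC", "TAT"  # extra tyrosines near the Trp side
    fr4 = scrub_motifs_in_frame(random_sense_codons(rng, 8), rng)
    seq = scrub_motifs_in_frame("".join(head), rng) + "TGG" + fr4
    return JSegment(
        name=f"JH{jh_index}",
        seq=seq,
        frame_offset=0,
        trp_offset=3 * k,
        cdr3_contribution_aa=k,
    )


def build_toy_locus(
    n_v: int,
    n_d: int = 4,
    n_j: int = 4,
    crss_fraction: float = 0.8,
    seed: int = 0,
) -> GermlineLocus:
    """Deterministic synthetic locus with planted selection-relevant features.

    The most proximal V is the VH5-2 (81X) analogue; the most proximal VH1
    is the VH1-11 analogue and uniquely encodes Gly97; alternate VH2 members
    encode Ser/Lys98; three V end in ``TA``.  Approximately *crss_fraction*
    of V carry the cryptic RSS, with VH5-2 and VH1-11 given priority since
    they are the canonical replacement recipients.
    """
    if n_v < 2 or n_d < 1 or n_j < 2:
        raise ValueError("need n_v >= 2, n_d >= 1, n_j >= 2")
    if not 0.0 <= crss_fraction <= 1.0:
        raise ValueError("crss_fraction must be in [0, 1]")
    rng = random.Random(seed)

    families = [_family_of_rank(r, n_v) for r in range(1, n_v + 1)]
    counters: dict[str, int] = {}
    names: list[str] = []
    for fam in families:
        i = counters.get(fam, 0)
        counters[fam] = i + 1
        plan = _FAMILY_NUMBERING.get(fam, [])
        num = plan[i] if i < len(plan) else 100 + i
        names.append(f"{fam}-{num}")

    n_crss = round(crss_fraction * n_v)
    priority = [i for i, nm in enumerate(names) if nm in ("VH5-2", "VH1-11")]
    rest = [i for i in range(n_v) if i not in priority]
    rng.shuffle(rest)
    crss_set = set((priority + rest)[:n_crss])

    # three TA-ending V: two without a cRSS plus one cRSS-bearing V that is
    # not one of the canonical replacement recipients
    no_crss = [i for i in range(n_v) if i not in crss_set]
    with_crss = [i for i in sorted(crss_set)
                 if names[i] not in ("VH5-2", "VH1-11")]
    ta_candidates = no_crss[:2] + with_crss[:1]
    ta_candidates += [i for i in no_crss[2:] + with_crss[1:]
                      if i not in ta_candidates]
    ta_set = set(ta_candidates[:3]) if n_v >= 3 else set()

    clan_table = load_default_clan_table()
    v_segments = []
    for idx, (rank, fam, name) in enumerate(zip(range(1, n_v + 1), families, names)):
        body = scrub_motifs_in_frame(random_sense_codons(rng, 94), rng)  # nt 0..282
        crss_part = CRSS if idx in crss_set else "TATTGTG"               # Tyr95-Cys96
        # codon 97 = last cRSS base 'G' + 2 nt: G+CC -> Ala (the common
        # case), G+GC -> Gly (the VH1-11 liability).  The V ends right
        # after codon 98, a few bases past the cRSS, so 3' trimming can
        # reach into the CDR3 start (and occasionally past Cys96).
        c97 = "GC" if name == "VH1-11" else "CC"
        # VH2 members carry the Ser/Lys98 liability; TA-enders get Leu98
        # spelled CTA; everyone else Arg98
        if idx in ta_set:
            c98 = "CTA"
        elif fam == "VH2":
            c98 = "AGC" if rank % 2 else "AAA"
        else:
            c98 = "CGT"
        coding = body + crss_part + c97 + c98
        assert len(coding) == V_LEN
        coding = scrub_motifs_in_frame(coding, rng, lock=(CRSS_NT, CRSS_NT + 7))
        v_segments.append(
            VSegment(
                name=name,
                locus_rank=rank,
                family=fam,
                clan=clan_of(name, clan_table),
                coding_seq=coding,
                fr3_seq=coding[FR3_START:FR3_END],
                rss_heptamer="CACA" + rng.choices("GAT", weights=[8, 1, 1])[0] + "TG",
                intergenic_3p=scrub_motifs(random_dna(rng, 120), rng),
                crss_offset=CRSS_NT if idx in crss_set else None,
            )
        )

    d_segments = [
        DSegment(
            name=_D_NAMES[i] if i < len(_D_NAMES) else f"DST{i + 1}",
            seq=_make_d(rng, want_rf3_stop=(i == 0 or (n_d > 2 and i == 2))),
        )
        for i in range(n_d)
    ]
    j_segments = [_make_j(rng, i + 1) for i in range(n_j)]
    return GermlineLocus(
        name=f"toy_igh_v{n_v}d{n_d}j{n_j}s{seed}",
        v_segments=v_segments,
        d_segments=d_segments,
        j_segments=j_segments,
    )


# --- serialisation -------------------------------------------------------

def write_locus(locus: GermlineLocus, fasta_path: str | Path, meta_path: str | Path) -> None:
    """FASTA (ids ``V|name`` etc.) plus a tab-separated metadata sidecar."""
    records = []
    rows = []
    for v in locus.v_segments:
        records.append(SeqRecord(Seq(v.coding_seq), id=f"V|{v.name}", description=""))
        rows.append(
            dict(
                name=v.name, type="V", locus_rank=v.locus_rank, family=v.family,
                clan=v.clan, crss_offset="" if v.crss_offset is None else v.crss_offset,
                frame_offset="", trp_offset="", rss_heptamer=v.rss_heptamer,
                fr3_seq=v.fr3_seq, intergenic_3p=v.intergenic_3p,
            )
        )
    for d in locus.d_segments:
        records.append(SeqRecord(Seq(d.seq), id=f"D|{d.name}", description=""))
        rows.append(dict(name=d.name, type="D", locus_rank="", family="", clan="",
                         crss_offset="", frame_offset="", trp_offset="",
                         rss_heptamer="", fr3_seq="", intergenic_3p=""))
    for j in locus.j_segments:
        records.append(SeqRecord(Seq(j.seq), id=f"J|{j.name}", description=""))
        rows.append(dict(name=j.name, type="J", locus_rank="", family="", clan="",
                         crss_offset="", frame_offset=j.frame_offset,
                         trp_offset=j.trp_offset, rss_heptamer="", fr3_seq="",
                         intergenic_3p=""))
    SeqIO.write(records, str(fasta_path), "fasta")
    pd.DataFrame(rows).to_csv(meta_path, sep="\t", index=False)


def read_locus(fasta_path: str | Path, meta_path: str | Path, name: str = "locus") -> GermlineLocus:
    seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta_path), "fasta")}
    meta = pd.read_csv(meta_path, sep="\t", dtype=str).fillna("")
    vs, ds, js = [], [], []
    for _, row in meta.iterrows():
        seq = seqs[f"{row['type']}|{row['name']}"]
        if row["type"] == "V":
            vs.append(
                VSegment(
                    name=row["name"], locus_rank=int(row["locus_rank"]),
                    family=row["family"],
                    clan=int(row["clan"]) if str(row["clan"]).isdigit() else row["clan"],
                    coding_seq=seq, fr3_seq=row["fr3_seq"],
                    rss_heptamer=row["rss_heptamer"],
                    intergenic_3p=row["intergenic_3p"],
                    crss_offset=int(row["crss_offset"]) if row["crss_offset"] != "" else None,
                )
            )
        elif row["type"] == "D":
            ds.append(DSegment(name=row["name"], seq=seq))
        else:
            js.append(
                JSegment(
                    name=row["name"], seq=seq,
                    frame_offset=int(row["frame_offset"]),
                    trp_offset=int(row["trp_offset"]),
                    cdr3_contribution_aa=(int(row["trp_offset"]) - int(row["frame_offset"])) // 3,
                )
            )
    return GermlineLocus(name=name, v_segments=vs, d_segments=ds, j_segments=js)
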