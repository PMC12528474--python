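"""Generative model of VDJ recombination and early B-cell selection.

The simulator produces the synthetic study populations used throughout the
package.  Its moving parts mirror the biology of the pro-B to small pre-B
("pre-B") transition:

* D-J joining first, on both alleles, then V to DJ in two recombination
  waves — an early wave strongly biased to D-proximal V (weights
  exp(-(rank-1)/tau1), modelling recombination before locus contraction)
  and a later, flatter wave;
* junctional diversification: geometric exonucleolytic trimming, Poisson
  non-templated (N) additions, short palindromic (P) additions on untrimmed
  V 3' and J 5' ends;
* Dmu arrest: a reading-frame-2 DJ allele expresses the truncated Dmu
  protein and arrests the cell before second-wave recombination (never in
  muMT mode, where membrane mu cannot signal);
* surrogate-light-chain (SLC) pairing: a productive mu chain pairs with
  probability base_pair_p (default 0.5 — about half of new mu chains fail)
  scaled by per-V, VH-family x JH, and CDR3-residue multipliers;
* VH-replacement (VHR): a stalled cell carrying a V with a cryptic RSS can
  have that V replaced by a locus-distal donor, excising a signal-joint
  circle (the ``PlantedCircle`` ground truth for the detector);
* allelic exclusion: a pairing mu chain stops all further recombination, so
  no surviving cell ever carries two pairing productive alleles.

Read-level emitters turn the populations into VDJseq-like (J-anchored,
UMI-tagged) and RCseq-like (framework-3 run-off) paired FASTQ libraries.
"""

from __future__ import annotations

import math
import random
from bisect import bisect_left
from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

from .locus_model import CYS_NT, DSegment, GermlineLocus, JSegment, VSegment
from .seqtools import ANY_MOTIF_RE, CRSS, random_dna, revcomp, translate

PRO_B = "pro-B"
LARGE_PRE_B = "large pre-B"
SMALL_PRE_B = "small pre-B"
ARRESTED = "arrested"
DEAD = "dead"


# --- parameters ----------------------------------------------------------

@dataclass
class JunctionParams:
    """Junctional diversity model: trimming, N and P additions (nt)."""

    trim_p: float = 0.25      # geometric 'stop trimming' probability per nt
    trim_max: int = 10
    n_lambda: float = 3.0     # mean non-templated nt per junction side
    n_max: int = 15
    p_nuc_max: int = 2        # palindromic nt, only on untrimmed ends

    def __post_init__(self) -> None:
        if min(self.trim_max, self.n_max, self.p_nuc_max) < 0:
            raise ValueError("bounds must be non-negative")
        if max(self.trim_max, self.n_max, self.p_nuc_max) > 20:
            raise ValueError("trim/N/P bounds must be <= 20 nt")

    @classmethod
    def zero(cls) -> "JunctionParams":
        return cls(trim_p=1.0, trim_max=0, n_lambda=0.0, n_max=0, p_nuc_max=0)


@dataclass
class SelectionParams:
    """Developmental selection model for the pro-B / pre-B transition."""

    dmu_arrest_p: float = 0.9
    base_pair_p: float = 0.5
    vh_pair_mult: dict = field(default_factory=dict)
    jh_short_mult: float = 0.3
    jh_short_families: tuple = ("VH2", "VH3", "VH5")
    jh_short_js: tuple = ("JH2", "JH3")
    residue_mults: dict = field(default_factory=dict)
    vhr_rate: float = 0.3
    vhr_rate_nonproductive_mult: float = 0.25
    insertion_range: tuple = (0, 4)
    mumt_mode: bool = False
    mumt_vhr_mult: float = 0.4
    tau1: float = 2.0          # proximal bias scale (ranks) of wave 1
    footprint_max: int = 7     # recipient nt retained 3' of the cRSS cut
    allow_second_replacement: bool = False

    def __post_init__(self) -> None:
        for p in (self.dmu_arrest_p, self.base_pair_p):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")

    @classmethod
    def default_for(cls, locus: GermlineLocus, **overrides) -> "SelectionParams":
        """Study-condition defaults: pairing deficits for proximal VH5/VH2/
        VH3 (VH5-2 worst), JH2/JH3 liability for those families, the
        residue-level selection observed in the repertoire (A97 over G97,
        against S/K98, for H99 and Y101, against the RF2-typical T/V), and
        a VHR rate giving stalled cells a realistic chance of rescue."""
        mult = {}
        for v in locus.v_segments:
            if v.locus_rank == 1:
                mult[v.name] = 0.05
            elif v.family == "VH5":
                mult[v.name] = 0.3
            elif v.family == "VH2":
                mult[v.name] = 0.4
            elif v.family == "VH3":
                mult[v.name] = 0.6
            elif v.family == "VH1":
                mult[v.name] = 1.4
            elif v.family == "VH14":
                mult[v.name] = 1.2
            else:
                mult[v.name] = 1.0
        residue = {
            (97, "G"): 0.25,
            (98, "S"): 0.5, (98, "K"): 0.5,
            (99, "H"): 2.0,
            (100, "T"): 0.55, (100, "V"): 0.55,
            (101, "T"): 0.55, (101, "V"): 0.55, (101, "Y"): 1.8,
            (102, "T"): 0.7, (102, "V"): 0.7,
        }
        return cls(vh_pair_mult=mult, residue_mults=residue, **overrides)


# --- allele and cell records --------------------------------------------

@dataclass
class DJAllele:
    d_name: str
    j_name: str
    d_rem: str          # D after 3' trimming (5' still intact)
    post_d: str         # N + P nucleotides between D and J
    j_trim: int
    d_rf: int           # Ichihara register imposed on the DJ transcript


@dataclass
class RecombinedAllele:
    v_name: str | None
    v_family: str | None
    d_name: str
    j_name: str
    junction_nt: str
    frame_shift: int
    has_stop: bool
    productive: bool
    d_rf: int | None
    read: str
    cdr3_aa: str | None
    wave: int
    replaced_from: str | None = None
    # provenance needed to replay the junction during VH-replacement
    _v_rem_len: int = 0
    _pre_d: str = ""
    _d_mid: str = ""
    _t5: int = 0
    _post_d: str = ""
    _j_trim: int = 0


@dataclass
class BCellRecord:
    cell_id: int
    stage: str
    alleles: list
    pairing: list = field(default_factory=list)
    stalled: bool = False
    allelically_excluded: bool = False


@dataclass
class PlantedCircle:
    recipient_v: str
    donor_v: str
    insertion: str
    circle_seq: str
    cell_id: int


# --- random draw helpers (single random.Random stream per simulation) ----

def _geom(rng: random.Random, p: float, cap: int) -> int:
    k = 0
    while k < cap and rng.random() > p:
        k += 1
    return k


def _pois(rng: random.Random, lam: float, cap: int) -> int:
    if lam <= 0:
        return 0
    limit = math.exp(-lam)
    k, prod = 0, rng.random()
    while prod > limit and k < cap:
        k += 1
        prod *= rng.random()
    return k


# --- recombination operations -------------------------------------------

def recombine_dj(d: DSegment, j: JSegment, params: JunctionParams, rng: random.Random,
                 max_retries: int = 50) -> DJAllele:
    """Join a D to a J: trim the D 3' end and the J 5' end, insert N
    nucleotides (plus P nucleotides on an untrimmed J end), and record the
    D reading frame the join imposes on a Dmu transcript."""
    for _ in range(max_retries):
        t3 = _geom(rng, params.trim_p, params.trim_max)
        if t3 <= len(d.seq) - 1:
            break
    else:
        raise RuntimeError("D segment consumed by trimming")
    j_trim = _geom(rng, params.trim_p, params.trim_max)
    p_j = revcomp(j.seq[: rng.randint(0, params.p_nuc_max)]) if (
        j_trim == 0 and params.p_nuc_max > 0) else ""
    n2 = random_dna(rng, _pois(rng, params.n_lambda, params.n_max))
    d_rem = d.seq[: len(d.seq) - t3]
    virtual_j_start = len(d_rem) + len(n2) + len(p_j) - j_trim
    d_rf = (virtual_j_start + j.frame_offset) % 3 + 1
    return DJAllele(d_name=d.name, j_name=j.name, d_rem=d_rem,
                    post_d=n2 + p_j, j_trim=j_trim, d_rf=d_rf)


def _build_allele(v: VSegment, v_rem: str, pre_d: str, d_mid: str, t5: int,
                  post_d: str, d_name: str, j: JSegment, j_trim: int,
                  wave: int, replaced_from: str | None = None) -> RecombinedAllele:
    j_rem = j.seq[j_trim:]
    read = v_rem + pre_d + d_mid + post_d + j_rem
    virtual_j_start = len(read) - len(j_rem) - j_trim
    frame_shift = (virtual_j_start + j.frame_offset) % 3
    w_pos = virtual_j_start + j.trp_offset
    scan = read[CYS_NT : w_pos + 3]
    has_stop = "*" in translate(scan)
    productive = frame_shift == 0 and not has_stop
    cdr3 = None
    if frame_shift == 0 and read[CYS_NT:CYS_NT + 3] in ("TGT", "TGC") \
            and read[w_pos:w_pos + 3] == "TGG":
        cdr3 = translate(read[CYS_NT + 3 : w_pos])
    d_rf = None
    if d_mid:
        d_read_pos = len(v_rem) + len(pre_d)
        d_rf = (t5 - d_read_pos) % 3 + 1
    return RecombinedAllele(
        v_name=v.name, v_family=v.family, d_name=d_name, j_name=j.name,
        junction_nt=scan, frame_shift=frame_shift, has_stop=has_stop,
        productive=productive, d_rf=d_rf, read=read, cdr3_aa=cdr3, wave=wave,
        replaced_from=replaced_from, _v_rem_len=len(v_rem), _pre_d=pre_d,
        _d_mid=d_mid, _t5=t5, _post_d=post_d, _j_trim=j_trim,
    )


def recombine_vdj(v: VSegment, dj: DJAllele, locus: GermlineLocus,
                  params: JunctionParams, rng: random.Random, wave: int = 1,
                  max_retries: int = 50) -> RecombinedAllele:
    """Join a V onto an existing DJ: trim the V 3' end and the D 5' end,
    insert N (and P on an untrimmed V end), and evaluate frame, stop codons,
    productivity and the Ichihara D reading frame of the final VDJ."""
    for _ in range(max_retries):
        t5 = _geom(rng, params.trim_p, params.trim_max)
        if t5 <= len(dj.d_rem) - 1:
            break
    else:
        raise RuntimeError("D remnant consumed by trimming")
    tv = _geom(rng, params.trim_p, params.trim_max)
    v_rem = v.coding_seq[: len(v.coding_seq) - tv]
    p_v = ""
    if tv == 0 and params.p_nuc_max > 0:
        k = rng.randint(0, params.p_nuc_max)
        p_v = revcomp(v.coding_seq[len(v.coding_seq) - k :]) if k else ""
    n1 = random_dna(rng, _pois(rng, params.n_lambda, params.n_max))
    j = locus.j_by_name[dj.j_name]
    return _build_allele(v, v_rem, p_v + n1, dj.d_rem[t5:], t5, dj.post_d,
                         dj.d_name, j, dj.j_trim, wave)


# --- selection operations -----------------------------------------------

def apply_dmu_arrest(cell: BCellRecord, params: SelectionParams, wave: int,
                     rng: random.Random) -> BCellRecord:
    """Dmu (RF2 DJ) developmental arrest before wave-2 recombination."""
    if wave == 1 or params.mumt_mode or cell.stage in (ARRESTED, DEAD):
        return cell
    has_rf2_dj = any(isinstance(a, DJAllele) and a.d_rf == 2 for a in cell.alleles)
    if has_rf2_dj and rng.random() < params.dmu_arrest_p:
        cell.stage = ARRESTED
    return cell


def slc_pairing_prob(allele: RecombinedAllele, cdr3: str | None,
                     params: SelectionParams) -> float:
    """Probability that a productive mu chain pairs with the SLC."""
    if not allele.productive:
        raise ValueError("pairing is only defined for productive alleles")
    p = params.base_pair_p * params.vh_pair_mult.get(allele.v_name, 1.0)
    if allele.v_family in params.jh_short_families and allele.j_name in params.jh_short_js:
        p *= params.jh_short_mult
    if cdr3:
        for i, aa in enumerate(cdr3):
            p *= params.residue_mults.get((97 + i, aa), 1.0)
    return min(1.0, max(0.0, p))


def attempt_vh_replacement(cell: BCellRecord, allele: RecombinedAllele,
                           locus: GermlineLocus, params: SelectionParams,
                           rng: random.Random,
                           counts: Counter | None = None):
    """One VHR attempt on *allele*; returns (new_allele, PlantedCircle) or
    None when nothing happened (no cRSS, rate draw failed, no distal donor)."""
    if cell.stage in (ARRESTED, DEAD):
        raise ValueError("arrested/dead cells cannot recombine")
    recipient = locus.v_by_name[allele.v_name]
    if recipient.crss_offset is None:
        return None
    if allele.replaced_from is not None and not params.allow_second_replacement:
        return None
    rate = params.vhr_rate
    if not allele.productive:
        rate *= params.vhr_rate_nonproductive_mult
    if params.mumt_mode:
        rate *= params.mumt_vhr_mult
    if rng.random() >= rate:
        return None
    donors = [v for v in locus.v_segments if v.locus_rank > recipient.locus_rank]
    if not donors:
        if counts is not None:
            counts["vhr_no_donor"] += 1
        return None
    donor = donors[rng.randrange(len(donors))]
    ins = random_dna(rng, rng.randint(*params.insertion_range))
    circle = PlantedCircle(
        recipient_v=recipient.name, donor_v=donor.name, insertion=ins,
        circle_seq=recipient.coding_seq[: recipient.crss_offset] + CRSS + ins
        + donor.rss_heptamer + donor.intergenic_3p,
        cell_id=cell.cell_id,
    )
    footprint = allele.read[recipient.crss_offset + 7 : allele._v_rem_len]
    footprint = footprint[: params.footprint_max]
    j = locus.j_by_name[allele.j_name]
    new_allele = _build_allele(
        donor, donor.coding_seq, footprint + allele._pre_d, allele._d_mid,
        allele._t5, allele._post_d, allele.d_name, j, allele._j_trim,
        wave=2, replaced_from=allele.v_name,
    )
    if counts is not None:
        counts["vhr_events"] += 1
    return new_allele, circle


# --- cohort simulation ---------------------------------------------------

@dataclass
class SimulationResult:
    cells: list
    circles: list
    pro_b_pool: list      # (cell_id, RecombinedAllele) at pro-B exit
    pre_b_pool: list      # (cell_id, RecombinedAllele) in small pre-B cells
    dj_pool: list         # (cell_id, DJAllele) never converted to VDJ
    counts: Counter
    locus: GermlineLocus

    def _frame(self, pool, stage: str) -> pd.DataFrame:
        clans = self.locus.clan_table()
        rows = [
            dict(
                cell_id=cid, stage=stage, v_call=a.v_name, family=a.v_family,
                clan=clans.get(a.v_name, "unknown"), d_call=a.d_name,
                j_call=a.j_name, d_rf=a.d_rf, frame_shift=a.frame_shift,
                stop_codon=a.has_stop, productive=a.productive,
                cdr3_aa=a.cdr3_aa, replaced_from=a.replaced_from, wave=a.wave,
            )
            for cid, a in pool
        ]
        return pd.DataFrame(rows)

    def pro_b_frame(self) -> pd.DataFrame:
        return self._frame(self.pro_b_pool, PRO_B)

    def pre_b_frame(self) -> pd.DataFrame:
        return self._frame(self.pre_b_pool, SMALL_PRE_B)

    def rearrangement_frame(self) -> pd.DataFrame:
        frames = [f for f in (self.pro_b_frame(), self.pre_b_frame()) if len(f)]
        return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()


def simulate_cohort(locus: GermlineLocus, jparams: JunctionParams,
                    sparams: SelectionParams, n_cells: int, n_steps: int = 3,
                    seed: int = 0) -> SimulationResult:
    """Simulate *n_cells* developing B cells; see the module docstring for
    the event order.  Deterministic for a given seed (one rng stream)."""
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    rng = random.Random(seed)
    vs = locus.v_segments
    w1 = [math.exp(-(v.locus_rank - 1) / sparams.tau1) for v in vs]
    cum1 = []
    acc = 0.0
    for w in w1:
        acc += w
        cum1.append(acc)
    total1 = cum1[-1]

    counts: Counter = Counter()
    cells, circles, pro_pool, pre_pool, dj_pool = [], [], [], [], []

    for cid in range(n_cells):
        djs = [
            recombine_dj(locus.d_segments[rng.randrange(len(locus.d_segments))],
                         locus.j_segments[rng.randrange(len(locus.j_segments))],
                         jparams, rng)
            for _ in range(2)
        ]
        cell = BCellRecord(cell_id=cid, stage=PRO_B, alleles=list(djs))
        final: list[RecombinedAllele] = []
        paired_allele = None

        for ai in (0, 1):
            wave = 1 if ai == 0 else 2
            apply_dmu_arrest(cell, sparams, wave, rng)
            if cell.stage == ARRESTED:
                counts["arrested"] += 1
                break
            if wave == 1:
                v = vs[bisect_left(cum1, rng.random() * total1)]
            else:
                v = vs[rng.randrange(len(vs))]
            allele = recombine_vdj(v, djs[ai], locus, jparams, rng, wave=wave)
            cell.alleles[ai] = allele
            counts["vdj_formed"] += 1

            if sparams.mumt_mode:
                for _ in range(n_steps):
                    res = attempt_vh_replacement(cell, allele, locus, sparams,
                                                 rng, counts)
                    if res is not None:
                        allele, circ = res
                        cell.alleles[ai] = allele
                        circles.append(circ)
                        counts["vdj_formed"] += 1
                final.append(allele)
                continue

            for _ in range(n_steps):
                if allele.productive:
                    if rng.random() < slc_pairing_prob(allele, allele.cdr3_aa, sparams):
                        paired_allele = allele
                        break
                    cell.stalled = True
                    res = attempt_vh_replacement(cell, allele, locus, sparams,
                                                 rng, counts)
                    if res is not None:
                        allele, circ = res
                        cell.alleles[ai] = allele
                        circles.append(circ)
                        counts["vdj_formed"] += 1
                else:
                    res = attempt_vh_replacement(cell, allele, locus, sparams,
                                                 rng, counts)
                    if res is None:
                        break  # NMD shortcut: move to the second allele
                    allele, circ = res
                    cell.alleles[ai] = allele
                    circles.append(circ)
                    counts["vdj_formed"] += 1
            final.append(allele)
            if paired_allele is not None:
                cell.allelically_excluded = True
                break

        if cell.stage != ARRESTED:
            if sparams.mumt_mode:
                cell.stage = PRO_B
            elif paired_allele is not None:
                cell.stage = SMALL_PRE_B
                cell.pairing = [a is paired_allele for a in final]
                counts["paired"] += 1
            elif any(a.productive for a in final):
                cell.stage = PRO_B  # stalled by a non-pairing mu chain
                counts["stalled_exit"] += 1
            else:
                cell.stage = DEAD
                counts["dead"] += 1

        pro_pool.extend((cid, a) for a in final)
        if cell.stage == SMALL_PRE_B:
            pre_pool.extend((cid, a) for a in final)
        dj_pool.extend((cid, a) for a in cell.alleles if isinstance(a, DJAllele))
        cells.append(cell)

    counts["cells"] = n_cells
    counts["circles"] = len(circles)
    return SimulationResult(cells=cells, circles=circles, pro_b_pool=pro_pool,
                            pre_b_pool=pre_pool, dj_pool=dj_pool, counts=counts,
                            locus=locus)


# --- read-level emitters -------------------------------------------------

VDJSEQ_FRAGMENT_START = 150   # V coordinate where VDJseq fragments begin
RCSEQ_FRAGMENT_START = 180    # V coordinate of the FR3 run-off primer
RCSEQ_INTERGENIC_KEEP = 80


@dataclass
class ReadPair:
    read_id: str
    r1: str
    r2: str


def _mutate(seq: str, rate: float, rng: random.Random) -> str:
    if rate <= 0:
        return seq
    s = None
    log1p = math.log1p(-rate)
    pos = -1
    while True:
        u = rng.random()
        pos += 1 + int(math.log(1.0 - u) / log1p)
        if pos >= len(seq):
            break
        if s is None:
            s = list(seq)
        s[pos] = rng.choice([b for b in "ACGT" if b != s[pos]])
    return seq if s is None else "".join(s)


def _emit_fragment(frag: str, mol_id: str, read_len: int, err_rate: float,
                   rng: random.Random, umi: str, n_copies: int,
                   reads: list) -> None:
    for c in range(n_copies):
        r1 = _mutate(frag[:read_len], err_rate, rng)
        r2 = _mutate(revcomp(frag[-read_len:]), err_rate, rng)
        reads.append(ReadPair(f"{mol_id}_UMI:{umi}_c{c}", r1, r2))


def emit_vdjseq_reads(pool, sampling_rate: float, read_len: int = 250,
                      err_rate: float = 0.001, rng: random.Random | None = None,
                      dup_lambda: float = 0.3):
    """J-anchored capture of a molecular sample of an allele pool.

    Each sampled allele yields one molecule (12-nt UMI); PCR duplicates are
    extra read pairs sharing the UMI.  Returns (reads, truth) where *truth*
    is the molecule table the deduplicator should recover.
    """
    if not 0.0 < sampling_rate <= 1.0:
        raise ValueError("sampling_rate must be in (0, 1]")
    rng = rng or random.Random(0)
    reads: list[ReadPair] = []
    truth_rows = []
    idx = 0
    for cid, allele in pool:
        if rng.random() >= sampling_rate:
            continue
        frag = allele.read[VDJSEQ_FRAGMENT_START:]
        umi = random_dna(rng, 12)
        n_copies = 1 + _pois(rng, dup_lambda, 20)
        mol = f"VDJ{idx}"
        _emit_fragment(frag, mol, read_len, err_rate, rng, umi, n_copies, reads)
        truth_rows.append(dict(molecule_id=mol, cell_id=cid, umi=umi,
                               v_call=allele.v_name, d_call=allele.d_name,
                               j_call=allele.j_name, productive=allele.productive,
                               sequence=frag, n_reads=n_copies))
        idx += 1
    return reads, pd.DataFrame(truth_rows)


def emit_dj_reads(dj_pool, locus: GermlineLocus, sampling_rate: float,
                  read_len: int = 250, err_rate: float = 0.001,
                  rng: random.Random | None = None, dup_lambda: float = 0.3):
    """DJ-only molecules (J-anchored capture also sees DJ recombinants)."""
    if not 0.0 < sampling_rate <= 1.0:
        raise ValueError("sampling_rate must be in (0, 1]")
    rng = rng or random.Random(0)
    reads, truth_rows = [], []
    for idx, (cid, dj) in enumerate(dj_pool):
        if rng.random() >= sampling_rate:
            continue
        flank = random_dna(rng, 30)
        while ANY_MOTIF_RE.search(flank):
            flank = random_dna(rng, 30)
        j = locus.j_by_name[dj.j_name]
        frag = flank + dj.d_rem + dj.post_d + j.seq[dj.j_trim:]
        umi = random_dna(rng, 12)
        n_copies = 1 + _pois(rng, dup_lambda, 20)
        mol = f"DJ{idx}"
        _emit_fragment(frag, mol, read_len, err_rate, rng, umi, n_copies, reads)
        truth_rows.append(dict(molecule_id=mol, cell_id=cid, umi=umi,
                               v_call=None, d_call=dj.d_name, j_call=dj.j_name,
                               productive=False, sequence=frag, n_reads=n_copies))
    return reads, pd.DataFrame(truth_rows)


def emit_rcseq_reads(circles, locus: GermlineLocus, primer_panel,
                     germline_background: int, read_len: int = 250,
                     err_rate: float = 0.0, rng: random.Random | None = None,
                     molecules_per_circle: int = 2):
    """FR3 run-off library: dominant germline background from the panel V
    plus reads traversing each replacement circle whose recipient is in the
    panel (FR3 -> V 3' end -> TACTGTG -> insertion -> donor heptamer ->
    donor intergenic)."""
    if not primer_panel:
        raise ValueError("primer_panel must not be empty")
    v_by_name = locus.v_by_name
    unknown = [n for n in primer_panel if n not in v_by_name]
    if unknown:
        raise ValueError(f"panel V not in locus: {unknown}")
    rng = rng or random.Random(0)
    panel = [v_by_name[n] for n in primer_panel]
    reads, truth_rows = [], []
    for i in range(germline_background):
        v = panel[rng.randrange(len(panel))]
        frag = (v.coding_seq[RCSEQ_FRAGMENT_START:] + v.rss_heptamer
                + v.intergenic_3p[:RCSEQ_INTERGENIC_KEEP])
        umi = random_dna(rng, 12)
        mol = f"BG{i}"
        _emit_fragment(frag, mol, read_len, err_rate, rng, umi, 1, reads)
        truth_rows.append(dict(molecule_id=mol, kind="background", v=v.name,
                               recipient=None, donor=None, insertion=None,
                               umi=umi, sequence=frag))
    panel_names = set(primer_panel)
    for k, circ in enumerate(circles):
        if circ.recipient_v not in panel_names:
            continue
        end = len(circ.circle_seq) - (120 - RCSEQ_INTERGENIC_KEEP)
        frag = circ.circle_seq[RCSEQ_FRAGMENT_START:end]
        for m in range(molecules_per_circle):
            umi = random_dna(rng, 12)
            mol = f"CIRC{k}.{m}"
            _emit_fragment(frag, mol, read_len, err_rate, rng, umi, 1, reads)
            truth_rows.append(dict(molecule_id=mol, kind="circle", v=None,
                                   recipient=circ.recipient_v, donor=circ.donor_v,
                                   insertion=circ.insertion, umi=umi,
                                   sequence=frag))
    return reads, pd.DataFrame(truth_rows)
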