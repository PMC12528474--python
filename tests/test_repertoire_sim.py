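"""Generative model: junction arithmetic, selection events, VH-replacement,
cohort invariants and read emitters, checked against independent oracles."""

import math
import random
from collections import Counter

import pytest
from Bio.Seq import Seq

from ighrep.locus_model import DSegment
from ighrep.repertoire_sim import (
    ARRESTED,
    BCellRecord,
    DJAllele,
    JunctionParams,
    PRO_B,
    SMALL_PRE_B,
    SelectionParams,
    _build_allele,
    apply_dmu_arrest,
    attempt_vh_replacement,
    emit_rcseq_reads,
    emit_vdjseq_reads,
    recombine_dj,
    recombine_vdj,
    simulate_cohort,
    slc_pairing_prob,
)
from ighrep.seqtools import revcomp


ZERO = JunctionParams.zero()


def _frame_compatible_d():
    # 18 nt (multiple of 3), stop-free in all codon-aligned reads
    return DSegment(name="D18", seq="GGTTATGGTTATACTGGG")


class TestRecombineDJ:
    def test_zero_params_exact_concatenation(self, locus30, rng):
        d, j = locus30.d_segments[0], locus30.j_segments[0]
        dj = recombine_dj(d, j, ZERO, rng)
        assert dj.d_rem == d.seq and dj.post_d == "" and dj.j_trim == 0
        # the imposed Dmu register follows from pure length arithmetic
        assert dj.d_rf == (len(d.seq) + j.frame_offset) % 3 + 1

    def test_n_insert_bounds(self, locus30):
        rng = random.Random(5)
        params = JunctionParams(trim_p=1.0, trim_max=0, n_lambda=3.0, n_max=15,
                                p_nuc_max=0)
        d, j = locus30.d_segments[1], locus30.j_segments[1]
        lengths = [len(recombine_dj(d, j, params, rng).post_d) for _ in range(1000)]
        assert all(0 <= n <= 15 for n in lengths)
        assert max(lengths) > 5  # Poisson(3) does explore the range

    def test_deterministic_under_seed(self, locus30):
        d, j = locus30.d_segments[0], locus30.j_segments[2]
        a = recombine_dj(d, j, JunctionParams(), random.Random(9))
        b = recombine_dj(d, j, JunctionParams(), random.Random(9))
        assert a == b


class TestRecombineVDJ:
    def test_frame_compatible_zero_params_productive(self, locus30, rng):
        v = locus30.v_segments[0]
        d = _frame_compatible_d()  # 300 + 18 + J all codon-aligned
        j = locus30.j_segments[0]
        dj = recombine_dj(d, j, ZERO, rng)
        allele = recombine_vdj(v, dj, locus30, ZERO, rng)
        assert allele.frame_shift == 0
        assert not allele.has_stop
        assert allele.productive
        assert allele.read == v.coding_seq + d.seq + j.seq

    def test_one_nt_insert_shifts_frame(self, locus30):
        v, d, j = locus30.v_segments[0], _frame_compatible_d(), locus30.j_segments[0]
        allele = _build_allele(v, v.coding_seq, "A", d.seq, 0, "", d.name, j, 0, wave=1)
        assert allele.frame_shift == 1
        assert not allele.productive

    def test_in_frame_stop_kills_productivity(self, locus30):
        v, d, j = locus30.v_segments[0], _frame_compatible_d(), locus30.j_segments[0]
        allele = _build_allele(v, v.coding_seq, "TAA", d.seq, 0, "", d.name, j, 0, wave=1)
        assert allele.frame_shift == 0
        assert allele.has_stop and not allele.productive

    def test_productive_iff_inframe_and_stopfree(self, locus30):
        rng = random.Random(3)
        jp = JunctionParams()
        for _ in range(300):
            d = locus30.d_segments[rng.randrange(4)]
            j = locus30.j_segments[rng.randrange(4)]
            v = locus30.v_segments[rng.randrange(30)]
            a = recombine_vdj(v, recombine_dj(d, j, jp, rng), locus30, jp, rng)
            assert a.productive == (a.frame_shift == 0 and not a.has_stop)


class TestDmuArrest:
    def _cell(self, d_rf):
        dj = DJAllele(d_name="D", j_name="JH1", d_rem="GGT", post_d="",
                      j_trim=0, d_rf=d_rf)
        return BCellRecord(cell_id=0, stage=PRO_B, alleles=[dj])

    def test_certain_arrest_in_wave2(self, rng):
        cell = self._cell(2)
        params = SelectionParams(dmu_arrest_p=1.0)
        assert apply_dmu_arrest(cell, params, wave=2, rng=rng).stage == ARRESTED

    def test_mumt_never_arrests(self, rng):
        cell = self._cell(2)
        params = SelectionParams(dmu_arrest_p=1.0, mumt_mode=True)
        assert apply_dmu_arrest(cell, params, wave=2, rng=rng).stage == PRO_B

    def test_wave1_and_rf1_unaffected(self, rng):
        params = SelectionParams(dmu_arrest_p=1.0)
        assert apply_dmu_arrest(self._cell(2), params, wave=1, rng=rng).stage == PRO_B
        assert apply_dmu_arrest(self._cell(1), params, wave=2, rng=rng).stage == PRO_B


class TestSlcPairing:
    def _productive_allele(self, locus, v_idx=0):
        rng = random.Random(1)
        d, j = _frame_compatible_d(), locus.j_segments[0]
        dj = recombine_dj(d, j, ZERO, rng)
        return recombine_vdj(locus.v_segments[v_idx], dj, locus, ZERO, rng)

    def test_neutral_default_is_half(self, locus30):
        allele = self._productive_allele(locus30)
        params = SelectionParams()  # no multipliers configured
        assert slc_pairing_prob(allele, None, params) == pytest.approx(0.5)

    def test_vh_multiplier_product(self, locus30):
        allele = self._productive_allele(locus30)
        params = SelectionParams(vh_pair_mult={allele.v_name: 0.05})
        assert slc_pairing_prob(allele, None, params) == pytest.approx(0.025)

    def test_clipped_at_one(self, locus30):
        allele = self._productive_allele(locus30)
        params = SelectionParams(vh_pair_mult={allele.v_name: 50.0})
        assert slc_pairing_prob(allele, None, params) == 1.0

    def test_residue_multipliers_apply_by_position(self, locus30):
        allele = self._productive_allele(locus30)
        cdr3 = allele.cdr3_aa
        assert cdr3  # zero-param junction on frame-compatible segments resolves
        params = SelectionParams(residue_mults={(97, cdr3[0]): 0.1})
        assert slc_pairing_prob(allele, cdr3, params) == pytest.approx(0.05)

    def test_nonproductive_rejected(self, locus30):
        v, d, j = locus30.v_segments[0], _frame_compatible_d(), locus30.j_segments[0]
        bad = _build_allele(v, v.coding_seq, "A", d.seq, 0, "", d.name, j, 0, wave=1)
        with pytest.raises(ValueError):
            slc_pairing_prob(bad, None, SelectionParams())


class TestVhReplacement:
    def _allele_for(self, locus, v):
        rng = random.Random(4)
        dj = recombine_dj(locus.d_segments[0], locus.j_segments[0],
                          JunctionParams(), rng)
        return recombine_vdj(v, dj, locus, JunctionParams(), rng)

    def test_most_distal_recipient_unchanged(self, locus_small, rng):
        counts = Counter()
        cell = BCellRecord(cell_id=1, stage=PRO_B, alleles=[])
        distal = locus_small.v_segments[-1]
        allele = self._allele_for(locus_small, distal)
        params = SelectionParams(vhr_rate=1.0, vhr_rate_nonproductive_mult=1.0)
        assert attempt_vh_replacement(cell, allele, locus_small, params, rng,
                                      counts) is None
        assert counts["vhr_no_donor"] == 1

    def test_rate_zero_always_unchanged(self, locus_small, rng):
        cell = BCellRecord(cell_id=1, stage=PRO_B, alleles=[])
        allele = self._allele_for(locus_small, locus_small.v_segments[0])
        params = SelectionParams(vhr_rate=0.0)
        for _ in range(50):
            assert attempt_vh_replacement(cell, allele, locus_small, params, rng) is None

    def test_planted_truth_over_draws(self, locus_small):
        """500 certain replacements of the most proximal V: donors all
        distal, circles structurally correct, D-J junction preserved."""
        rng = random.Random(8)
        recipient = locus_small.v_segments[0]
        allele = self._allele_for(locus_small, recipient)
        cell = BCellRecord(cell_id=2, stage=PRO_B, alleles=[])
        params = SelectionParams(vhr_rate=1.0, vhr_rate_nonproductive_mult=1.0)
        ranks = {v.name: v.locus_rank for v in locus_small.v_segments}
        donor_names = set()
        for _ in range(500):
            new_allele, circle = attempt_vh_replacement(cell, allele,
                                                        locus_small, params, rng)
            assert ranks[circle.donor_v] > ranks[circle.recipient_v]
            donor_names.add(circle.donor_v)
            donor = locus_small.v_by_name[circle.donor_v]
            expected = (recipient.coding_seq[: recipient.crss_offset]
                        + "TACTGTG" + circle.insertion + donor.rss_heptamer
                        + donor.intergenic_3p)
            assert circle.circle_seq == expected
            assert 0 <= len(circle.insertion) <= 4
            # the recipient's D-J junction nucleotides survive verbatim
            assert (new_allele._d_mid, new_allele._post_d, new_allele._j_trim) == \
                (allele._d_mid, allele._post_d, allele._j_trim)
            assert new_allele.read.endswith(
                allele.read[allele._v_rem_len + len(allele._pre_d):])
            assert new_allele.replaced_from == recipient.name
        assert donor_names == {v.name for v in locus_small.v_segments[1:]}

    def test_no_crss_recipient_never_replaced(self, locus30, rng):
        no_crss = next(v for v in locus30.v_segments if v.crss_offset is None)
        allele = self._allele_for(locus30, no_crss)
        cell = BCellRecord(cell_id=3, stage=PRO_B, alleles=[])
        params = SelectionParams(vhr_rate=1.0, vhr_rate_nonproductive_mult=1.0)
        for _ in range(20):
            assert attempt_vh_replacement(cell, allele, locus30, params, rng) is None


class TestSimulateCohort:
    def test_mumt_blocks_progression(self, locus30):
        sp = SelectionParams.default_for(locus30, mumt_mode=True)
        sim = simulate_cohort(locus30, JunctionParams(), sp, n_cells=400, seed=3)
        stages = {c.stage for c in sim.cells}
        assert stages <= {PRO_B, ARRESTED}

    def test_vhr_zero_no_circles(self, locus30):
        sp = SelectionParams.default_for(locus30, vhr_rate=0.0)
        sim = simulate_cohort(locus30, JunctionParams(), sp, n_cells=400, seed=3)
        assert sim.circles == []

    def test_allelic_exclusion(self, locus30):
        sp = SelectionParams.default_for(locus30)
        sim = simulate_cohort(locus30, JunctionParams(), sp, n_cells=2000, seed=11)
        for cell in sim.cells:
            if cell.stage == SMALL_PRE_B:
                assert sum(cell.pairing) <= 1

    def test_circle_invariants_in_cohort(self, wt_sim):
        ranks = {v.name: v.locus_rank for v in wt_sim.locus.v_segments}
        assert len(wt_sim.circles) > 0
        for c in wt_sim.circles:
            assert ranks[c.donor_v] > ranks[c.recipient_v]

    def test_circle_count_linear_in_vhr_rate(self, locus30):
        rates = [0.05, 0.10, 0.15]
        counts = []
        for i, r in enumerate(rates):
            sp = SelectionParams.default_for(locus30, vhr_rate=r, mumt_mode=True)
            sim = simulate_cohort(locus30, JunctionParams(), sp,
                                  n_cells=20000, seed=40 + i)
            counts.append(len(sim.circles))
        from ighrep.selection_stats import linear_r2

        assert counts[0] < counts[1] < counts[2]
        assert linear_r2(rates, counts) > 0.98

    def test_productive_fraction_matches_junction_model(self, locus30):
        """Cohort productivity equals an independent junction-model
        expectation: closed-form in-frame probability (mod-3 convolution of
        the trim/N/P distributions) times a Monte-Carlo stop-free rate."""
        jp = JunctionParams()
        p_inframe = _closed_form_inframe(locus30, jp)
        mc_prod, mc_inframe = _mc_junction_model(locus30, jp, n=40000, seed=77)
        assert mc_inframe == pytest.approx(p_inframe, abs=0.01)
        sp = SelectionParams.default_for(locus30, vhr_rate=0.0)
        sim = simulate_cohort(locus30, jp, sp, n_cells=25000, seed=7)
        observed = sim.pro_b_frame()["productive"].mean()
        assert observed == pytest.approx(mc_prod, abs=0.03)


# --- independent junction-model oracle -----------------------------------

def _geom_pmf(p, cap):
    pmf = {k: p * (1 - p) ** k for k in range(cap)}
    pmf[cap] = (1 - p) ** cap
    return pmf


def _pois_pmf(lam, cap):
    pmf = {}
    acc = 0.0
    for k in range(cap):
        pk = math.exp(-lam) * lam ** k / math.factorial(k)
        pmf[k] = pk
        acc += pk
    pmf[cap] = 1.0 - acc
    return pmf


def _mod3(pmf_pairs):
    out = [0.0, 0.0, 0.0]
    for val, p in pmf_pairs:
        out[val % 3] += p
    return out


def _conv3(a, b):
    return [sum(a[i] * b[(k - i) % 3] for i in range(3)) for k in range(3)]


def _closed_form_inframe(locus, jp):
    trim = _geom_pmf(jp.trim_p, jp.trim_max)
    nins = _pois_pmf(jp.n_lambda, jp.n_max)
    # V end: -trim, plus uniform 0..2 P nt when untrimmed
    v_end = []
    for t, pt in trim.items():
        if t == 0:
            for pv in range(jp.p_nuc_max + 1):
                v_end.append((pv - t, pt / (jp.p_nuc_max + 1)))
        else:
            v_end.append((-t, pt))
    j_end = v_end  # same structure on the J 5' side
    n_side = list(nins.items())
    base = _conv3(_mod3(v_end), _mod3(n_side))
    base = _conv3(base, _mod3(n_side))
    base = _conv3(base, _mod3(j_end))
    total = 0.0
    for d in locus.d_segments:
        L = len(d.seq)
        # joint (t3, t5) with resampling keeping at least 1 nt of D
        d_pairs = []
        z3 = sum(pt for t, pt in trim.items() if t <= L - 1)
        for t3, p3 in trim.items():
            if t3 > L - 1:
                continue
            z5 = sum(pt for t, pt in trim.items() if t <= L - t3 - 1)
            for t5, p5 in trim.items():
                if t5 > L - t3 - 1:
                    continue
                d_pairs.append((L - t3 - t5, (p3 / z3) * (p5 / z5)))
        dist = _conv3(base, _mod3(d_pairs))
        total += dist[0] / len(locus.d_segments)
    return total  # V length and J frame offsets are multiples of 3


def _draw(rng, pmf):
    u = rng.random()
    acc = 0.0
    for k, p in pmf.items():
        acc += p
        if u <= acc:
            return k
    return k


def _mc_junction_model(locus, jp, n, seed):
    """Assemble junctions directly from the documented distributions and
    translate with Biopython; independent of the simulator's code path."""
    rng = random.Random(seed)
    trim = _geom_pmf(jp.trim_p, jp.trim_max)
    nins = _pois_pmf(jp.n_lambda, jp.n_max)
    prod = inframe = 0
    for _ in range(n):
        v = locus.v_segments[rng.randrange(len(locus.v_segments))]
        d = locus.d_segments[rng.randrange(len(locus.d_segments))]
        j = locus.j_segments[rng.randrange(len(locus.j_segments))]
        while True:
            t3 = _draw(rng, trim)
            if t3 <= len(d.seq) - 1:
                break
        while True:
            t5 = _draw(rng, trim)
            if t5 <= len(d.seq) - t3 - 1:
                break
        tv = _draw(rng, trim)
        tj = _draw(rng, trim)
        pv = rng.randint(0, jp.p_nuc_max) if tv == 0 else 0
        pj = rng.randint(0, jp.p_nuc_max) if tj == 0 else 0
        n1 = "".join(rng.choice("ACGT") for _ in range(_draw(rng, nins)))
        n2 = "".join(rng.choice("ACGT") for _ in range(_draw(rng, nins)))
        vpart = v.coding_seq[: len(v.coding_seq) - tv]
        vpart += revcomp(v.coding_seq[len(v.coding_seq) - pv :]) if pv else ""
        jrem = j.seq[tj:]
        pjs = revcomp(j.seq[:pj]) if pj else ""
        seq = vpart + n1 + d.seq[t5 : len(d.seq) - t3] + n2 + pjs + jrem
        j_start = len(seq) - len(jrem) - tj
        ok_frame = (j_start + j.frame_offset) % 3 == 0
        inframe += ok_frame
        if ok_frame:
            w_pos = j_start + j.trp_offset
            pep = str(Seq(seq[285 : w_pos + 3]).translate())
            prod += "*" not in pep
    return prod / n, inframe / n


class TestEmitters:
    def test_vdjseq_full_sampling_counts(self, wt_sim):
        rng = random.Random(1)
        reads, truth = emit_vdjseq_reads(wt_sim.pro_b_pool[:500], sampling_rate=1.0,
                                         err_rate=0.0, dup_lambda=0.0, rng=rng)
        assert len(truth) == 500 and len(reads) == 500

    def test_duplicates_exceed_umis(self, wt_sim):
        rng = random.Random(2)
        reads, truth = emit_vdjseq_reads(wt_sim.pro_b_pool[:500], sampling_rate=1.0,
                                         err_rate=0.0, dup_lambda=1.0, rng=rng)
        assert len(reads) > truth["umi"].nunique()

    def test_error_free_reads_match_source(self, wt_sim):
        rng = random.Random(3)
        pool = wt_sim.pro_b_pool[:200]
        reads, truth = emit_vdjseq_reads(pool, sampling_rate=1.0, err_rate=0.0,
                                         dup_lambda=0.0, rng=rng)
        frags = dict(zip(truth["molecule_id"], truth["sequence"]))
        by_read = {f"VDJ{i}": a.read for i, (_, a) in enumerate(pool)}
        for r in reads:
            mol = r.read_id.split("_UMI")[0]
            assert frags[mol] in by_read[mol]
            assert r.r1 == frags[mol][: len(r.r1)]
            assert revcomp(r.r2) == frags[mol][-len(r.r2):]

    def test_rcseq_background_only(self, locus30):
        rng = random.Random(4)
        panel = [v.name for v in locus30.v_segments if v.crss_offset is not None]
        reads, truth = emit_rcseq_reads([], locus30, panel,
                                        germline_background=1000, rng=rng)
        assert len(reads) == 1000
        import re

        junction = re.compile(r"TACTGTG[ACGT]{0,4}CACA[GAT]TG")
        assert not any(junction.search(r.r1) for r in reads)

    def test_rcseq_panel_filter(self, locus30, wt_sim):
        rng = random.Random(5)
        circ = wt_sim.circles[0]
        other = [v.name for v in locus30.v_segments
                 if v.crss_offset is not None and v.name != circ.recipient_v][:3]
        reads, truth = emit_rcseq_reads([circ], locus30, other,
                                        germline_background=10, rng=rng)
        assert (truth["kind"] == "circle").sum() == 0
        reads2, truth2 = emit_rcseq_reads([circ], locus30, [circ.recipient_v],
                                          germline_background=0, rng=rng)
        assert (truth2["kind"] == "circle").sum() >= 1
        wanted = "TACTGTG" + circ.insertion
        assert any(wanted in r.r1 for r in reads2)

    def test_empty_panel_rejected(self, locus30):
        with pytest.raises(ValueError):
            emit_rcseq_reads([], locus30, [], germline_background=10)
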