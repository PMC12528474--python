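"""Repertoire-level selection statistics.

All functions operate on an annotated rearrangement DataFrame (columns
``v_call, family, clan, j_call, productive, d_rf, frame_shift, stop_codon,
cdr3_aa, stage``; CDR3 position 97+i is simply ``cdr3_aa[i]``, because the
CDR3 is numbered from 97 right after the invariant Cys96).

Conventions:

* frequency tables carry their denominator, and rare keys pooled below a
  frequency threshold stay in the denominator;
* fold changes with a zero baseline are reported as undefined, never
  infinite;
* positional statistics use only rows whose CDR3 resolved the position
  (numerator and denominator alike);
* net CDR3 charge counts R/K as +1 and D/E as -1 and ignores His by
  default (pKa near 7); GRAVY is the mean Kyte-Doolittle hydropathy; the
  aliphatic index is 100*(fA + 2.9 fV + 3.9 (fI + fL)).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from Bio.SeqUtils.ProtParamData import kd as KYTE_DOOLITTLE


STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")


def _subset(rows: pd.DataFrame, subset: dict | None) -> pd.DataFrame:
    if not subset:
        return rows
    out = rows
    for col, val in subset.items():
        out = out[out[col] == val]
    return out


# --- frequency tables ----------------------------------------------------

@dataclass
class FrequencyTable:
    counts: pd.Series
    denominator: int
    subset: str = ""
    pooled_other: int = 0

    @property
    def freq(self) -> pd.Series:
        if self.denominator == 0:
            return self.counts.astype(float)
        return self.counts / self.denominator

    def full_freq(self) -> pd.Series:
        """Frequencies including the pooled 'other' bucket (sums to 1)."""
        s = self.freq
        if self.pooled_other:
            s = pd.concat([s, pd.Series({"other": self.pooled_other / self.denominator})])
        return s


def vh_frequency(rows: pd.DataFrame, subset: dict | None = None,
                 min_freq: float = 0.0, key: str = "v_call") -> FrequencyTable:
    """Per-key frequency table within a subset.  Keys below *min_freq* are
    pooled into 'other' but stay in the denominator."""
    sel = _subset(rows, subset)
    sel = sel[sel[key].notna()]
    if len(sel) == 0:
        warnings.warn("empty subset for vh_frequency")
        return FrequencyTable(counts=pd.Series(dtype=int), denominator=0,
                              subset=repr(subset))
    counts = sel[key].value_counts()
    denom = int(counts.sum())
    keep = counts[counts / denom >= min_freq]
    pooled = denom - int(keep.sum())
    return FrequencyTable(counts=keep, denominator=denom,
                          subset=repr(subset), pooled_other=pooled)


def selection_fold(table_a: FrequencyTable, table_b: FrequencyTable) -> pd.DataFrame:
    """Per-key change from a to b: fold (b/a; undefined when a is 0) and
    difference (b - a)."""
    keys = table_a.counts.index.union(table_b.counts.index)
    fa = table_a.freq.reindex(keys, fill_value=0.0)
    fb = table_b.freq.reindex(keys, fill_value=0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        fold = fb / fa
    out = pd.DataFrame({"freq_a": fa, "freq_b": fb,
                        "fold": fold.where(fa > 0, np.nan),
                        "diff": fb - fa})
    out["fold_undefined"] = fa == 0
    return out


def productivity_by_vh(rows: pd.DataFrame, min_n: int = 20) -> pd.DataFrame:
    """Fraction of VDJ that are productive, per V."""
    sel = rows[rows["v_call"].notna() & rows["productive"].notna()]
    grp = sel.groupby("v_call")["productive"]
    out = pd.DataFrame({"n": grp.size(), "productive_fraction": grp.mean()})
    out["low_n"] = out["n"] < min_n
    return out


def vh_family_by_jh(rows: pd.DataFrame, families, subset: dict | None = None) -> pd.DataFrame:
    """Fractions of the entire VDJ repertoire per (family, JH) cell."""
    sel = _subset(rows, subset)
    sel = sel[sel["v_call"].notna()]
    total = len(sel)
    mat = (sel[sel["family"].isin(families)]
           .groupby(["family", "j_call"]).size().unstack(fill_value=0))
    return mat.reindex(families, fill_value=0) / max(total, 1)


# --- positional amino-acid statistics ------------------------------------

def _residue_at(rows: pd.DataFrame, position: int) -> pd.Series:
    """CDR3 residue at an absolute position (97-based), NaN when unresolved."""
    idx = position - 97
    cdr3 = rows["cdr3_aa"]
    return cdr3.where(cdr3.notna()).map(
        lambda s: s[idx] if isinstance(s, str) and 0 <= idx < len(s) else np.nan)


def residue_freq_at(rows: pd.DataFrame, position: int, residue: str,
                    group_by: str | None = None,
                    exclusions: dict | None = None) -> pd.Series:
    """Frequency of *residue* at CDR3 *position* among rows that resolve the
    position, per group.  *exclusions* maps column -> values to drop
    (e.g. {'v_call': ['VH1-11']})."""
    sel = rows
    for col, vals in (exclusions or {}).items():
        sel = sel[~sel[col].isin(vals)]
    res = _residue_at(sel, position)
    ok = res.notna()
    if group_by is None:
        n = int(ok.sum())
        if n == 0:
            warnings.warn(f"no rows resolve position {position}")
            return pd.Series(dtype=float)
        return pd.Series({"all": float((res[ok] == residue).sum()) / n})
    out = {}
    for g, sub in res.groupby(sel[group_by]):
        n = int(sub.notna().sum())
        if n == 0:
            warnings.warn(f"group {g} never resolves position {position}")
            continue
        out[g] = float((sub == residue).sum()) / n
    return pd.Series(out)


def positional_delta(rows_a: pd.DataFrame, rows_b: pd.DataFrame, families,
                     positions=range(97, 104)) -> pd.DataFrame:
    """Tidy per-(family, position, aa) change in residue frequency between
    two repertoires; deltas sum to zero within each (family, position)."""
    recs = []
    for fam in families:
        a = rows_a[rows_a["family"] == fam]
        b = rows_b[rows_b["family"] == fam]
        for pos in positions:
            ra, rb = _residue_at(a, pos).dropna(), _residue_at(b, pos).dropna()
            if len(ra) == 0 or len(rb) == 0:
                continue
            fa, fb = ra.value_counts(normalize=True), rb.value_counts(normalize=True)
            for aa in fa.index.union(fb.index):
                recs.append(dict(family=fam, position=pos, aa=aa,
                                 freq_a=fa.get(aa, 0.0), freq_b=fb.get(aa, 0.0),
                                 delta=fb.get(aa, 0.0) - fa.get(aa, 0.0)))
    return pd.DataFrame(recs)


# --- reading frames and stop codons --------------------------------------

def rf_and_stop_summary(rows: pd.DataFrame, group_by: str | None = None):
    """(RF relative frequencies, in-frame stop-codon fraction per RF)."""
    sel = rows[rows["d_rf"].notna()]
    keys = [group_by] if group_by else []
    if group_by:
        rf = (sel.groupby(keys + ["d_rf"]).size()
              / sel.groupby(keys).size()).rename("freq").reset_index()
    else:
        rf = (sel["d_rf"].value_counts(normalize=True)
              .rename("freq").rename_axis("d_rf").reset_index())
    inframe = sel[sel["frame_shift"] == 0]
    if group_by:
        stops = inframe.groupby(keys + ["d_rf"])["stop_codon"].mean().rename(
            "stop_fraction").reset_index()
    else:
        stops = inframe.groupby("d_rf")["stop_codon"].mean().rename(
            "stop_fraction").reset_index()
    return rf, stops


# --- biophysics ----------------------------------------------------------

def cdr3_biophysics(cdr3: str, his_charge: float = 0.0):
    """(net_charge, gravy, aliphatic_index, length) for a CDR3 peptide."""
    aas = [a for a in cdr3 if a in STANDARD_AA]
    skipped = len(cdr3) - len(aas)
    if skipped:
        warnings.warn(f"{skipped} non-standard residues excluded")
    n = len(aas)
    charge = (cdr3.count("R") + cdr3.count("K")) - (cdr3.count("D") + cdr3.count("E"))
    charge = charge + his_charge * cdr3.count("H")
    if n == 0:
        return charge, float("nan"), float("nan"), len(cdr3)
    gravy = sum(KYTE_DOOLITTLE[a] for a in aas) / n
    fa = aas.count("A") / n
    fv = aas.count("V") / n
    fil = (aas.count("I") + aas.count("L")) / n
    aliphatic = 100.0 * (fa + 2.9 * fv + 3.9 * fil)
    return charge, gravy, aliphatic, len(cdr3)


def weighted_logo(d_segments, usage_weights: dict, rf: int) -> pd.DataFrame:
    """Position frequency matrix of D-region residues in reading frame *rf*,
    weighted by D usage.  Stops appear as 'X'; columns sum to <= 1 because
    short D contribute nothing past their length."""
    total = sum(usage_weights.get(d.name, 0.0) for d in d_segments)
    if not np.isclose(total, 1.0):
        raise ValueError("usage weights must sum to 1 over the D segments")
    cols: dict[int, dict[str, float]] = {}
    for d in d_segments:
        w = usage_weights.get(d.name, 0.0)
        pep = d.rf_peptides[rf - 1].replace("*", "X")
        for i, aa in enumerate(pep):
            cols.setdefault(i + 1, {}).setdefault(aa, 0.0)
            cols[i + 1][aa] += w
    return pd.DataFrame(cols).fillna(0.0).T.sort_index()


# --- inference -----------------------------------------------------------

def linear_r2(x, y) -> float | None:
    """Coefficient of determination of simple linear regression y ~ x."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length vectors, n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("zero variance; R^2 undefined")
        return None
    res = sps.linregress(x, y)
    return float(res.rvalue ** 2)


def welch_t(a, b):
    """Welch's unequal-variance t test: (t, Satterthwaite df, two-sided p)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = len(a), len(b)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            return 0.0, float(na + nb - 2), 1.0
        raise ValueError("both groups have zero variance")
    se2 = va / na + vb / nb
    t = (a.mean() - b.mean()) / np.sqrt(se2)
    df = se2 ** 2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * sps.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def bh_qvalues(pvals) -> np.ndarray:
    """Benjamini-Hochberg q-values (additive convenience, off by default in
    the CLI report)."""
    p = np.asarray(pvals, dtype=float)
    order = np.argsort(p)
    ranked = p[order] * len(p) / (np.arange(len(p)) + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty_like(q)
    out[order] = np.clip(q, 0, 1)
    return out


def crss_productivity_association(v_meta: pd.DataFrame,
                                  productivity_table: pd.DataFrame,
                                  min_group: int = 2) -> dict | None:
    """Compare per-V productivity between V with and without a cryptic RSS.

    *v_meta* needs columns ``name, has_crss, ends_ta``; *productivity_table*
    is the output of :func:`productivity_by_vh`.  Returns medians, the Welch
    test and the TA-terminal flags, or None when a group is too small.
    """
    merged = v_meta.set_index("name").join(productivity_table, how="inner")
    has = merged[merged["has_crss"]]["productive_fraction"].dropna()
    hasnt = merged[~merged["has_crss"]]["productive_fraction"].dropna()
    if len(has) < min_group or len(hasnt) < min_group:
        return None
    t, df, p = welch_t(has, hasnt)
    return dict(
        has_crss_values=has, no_crss_values=hasnt,
        median_has=float(has.median()), median_no=float(hasnt.median()),
        t=t, df=df, p=p,
        ta_flagged=list(merged[merged["ends_ta"]].index),
    )


# --- deposited-data recomputation ----------------------------------------

def recompute_deposited_fractions(mumt_path, prob_nonproductive_path):
    """Recompute headline fractions from deposited AIRR rearrangement TSVs.

    Returns (muMT productive VDJ fraction, VH5-2 share of pro-B
    non-productive VDJ), both as percentages.  The tables must carry
    ``v_call`` and ``productive`` columns in AIRR format.
    """
    mumt = pd.read_csv(mumt_path, sep="\t")
    prob = pd.read_csv(prob_nonproductive_path, sep="\t")
    for frame in (mumt, prob):
        if frame["productive"].dtype == object:
            frame["productive"] = frame["productive"].isin([True, "T", "TRUE", "True", "true"])
    vdj = mumt[mumt["v_call"].notna()]
    productive_pct = 100.0 * vdj["productive"].mean()
    nonprod = prob[prob["v_call"].notna() & ~prob["productive"]]
    vh52 = nonprod["v_call"].astype(str).str.contains("5-2|81X", regex=True)
    vh52_pct = 100.0 * vh52.mean()
    return float(productive_pct), float(vh52_pct)
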