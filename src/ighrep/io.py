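"""FASTQ round-tripping and the merge+dedup front end of the pipeline."""

from __future__ import annotations

import gzip
from pathlib import Path

from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .annotate import dedup_by_umi, merge_pairs


def _open(path, mode):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode + "t")
    return open(path, mode)


def write_fastq_pairs(reads, r1_path: str | Path, r2_path: str | Path) -> None:
    """Write ReadPair records as two FASTQ files (constant quality)."""
    with _open(r1_path, "w") as f1, _open(r2_path, "w") as f2:
        for r in reads:
            f1.write(f"@{r.read_id}\n{r.r1}\n+\n{'I' * len(r.r1)}\n")
            f2.write(f"@{r.read_id}\n{r.r2}\n+\n{'I' * len(r.r2)}\n")


def read_fastq_pairs(r1_path: str | Path, r2_path: str | Path):
    """Yield (title, seq1, qual1, seq2, qual2) for mate pairs."""
    with _open(r1_path, "r") as f1, _open(r2_path, "r") as f2:
        for (t1, s1, q1), (t2, s2, q2) in zip(FastqGeneralIterator(f1),
                                              FastqGeneralIterator(f2)):
            if t1.split()[0] != t2.split()[0]:
                raise ValueError(f"mate order mismatch: {t1} vs {t2}")
            yield t1, s1, q1, s2, q2


def merge_and_dedup(pairs, min_overlap: int = 20, max_mismatch_frac: float = 0.1):
    """Merge read pairs and collapse PCR duplicates.

    *pairs* yields (title, seq1, qual1, seq2, qual2).  Returns
    (molecules, counts) where counts itemises unmerged and unparsed reads.
    """
    merged = []
    counts = {"pairs": 0, "unmerged": 0}
    for title, s1, q1, s2, q2 in pairs:
        counts["pairs"] += 1
        cons = merge_pairs(s1, s2, min_overlap=min_overlap,
                           max_mismatch_frac=max_mismatch_frac)
        if cons is None:
            counts["unmerged"] += 1
            continue
        merged.append((title, cons, "I" * len(cons)))
    molecules, sink = dedup_by_umi(merged)
    counts.update(sink)
    counts["molecules"] = len(molecules)
    return molecules, counts
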