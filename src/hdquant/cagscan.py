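"""CAG-run detection in transcript sequences and DEG enrichment testing.

Three consecutive CAG units are the shortest tract able to form a slipped
hairpin, so transcripts carrying a (CAG)>=3 run are the candidate off-target
set for slip-out-binding ligands.  Whether differentially expressed genes
are enriched for such transcripts is assessed with a two-sided Fisher's
exact test on the 2x2 table of DEG status by CAG-run status.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "scan_cag",
    "scan_fasta",
    "fisher_exact_2x2",
    "test_enrichment",
    "EnrichmentResult",
]


def scan_cag(sequence: str, min_units: int = 3, both_strands: bool = False) -> tuple[bool, int]:
    """Longest run of consecutive CAG units in a nucleotide sequence.

    The run is the literal contiguous substring (CAG)^k at any offset;
    phase rotations (AGC/GCA) without the full 9-mer do not count, and any
    non-CAG base, including N, breaks a run.  Case-insensitive.  With
    ``both_strands`` the reverse-complement motif CTG is scanned as well
    and the longer run is reported.

    Returns ``(contains_run, max_run_units)``.
    """
    if min_units < 1:
        raise ValueError("min_units must be >= 1")
    seq = sequence.upper()
    if seq and set(seq) - set("ACGTN"):
        raise ValueError("sequence must be over A, C, G, T, N")
    best = _max_unit_run(seq, "CAG")
    if both_strands:
        best = max(best, _max_unit_run(seq, "CTG"))
    return best >= min_units, best


def _max_unit_run(seq: str, unit: str) -> int:
    best = 0
    k = len(unit)
    i = 0
    n = len(seq)
    while i + k <= n:
        if seq[i:i + k] == unit:
            j = i
            while j + k <= n and seq[j:j + k] == unit:
                j += k
            best = max(best, (j - i) // k)
            i += 1  # re-test shifted offsets; runs can start at any phase
        else:
            i += 1
    return best


def scan_fasta(path, min_units: int = 3, both_strands: bool = False) -> pd.DataFrame:
    """Scan every record of a FASTA file; returns (gene, contains_run, max_run_units)."""
    from Bio import SeqIO

    rows = []
    for rec in SeqIO.parse(str(path), "fasta"):
        contains, units = scan_cag(str(rec.seq), min_units, both_strands)
        rows.append({"gene": rec.id, "contains_run": contains, "max_run_units": units})
    return pd.DataFrame(rows)


@dataclass
class EnrichmentResult:
    table: np.ndarray  # [[DEG & CAG, DEG & not], [non-DEG & CAG, non-DEG & not]]
    odds_ratio: float
    p_two_sided: float


def fisher_exact_2x2(table) -> tuple[float, float]:
    """Fisher's exact test on a 2x2 count table.

    The odds ratio is the sample odds ratio (a*d)/(b*c); it is ``inf`` when
    b*c = 0 with a*d > 0 and ``nan`` when both products vanish.  The
    two-sided p-value sums hypergeometric probabilities of all tables with
    the observed margins whose probability does not exceed the observed
    table's (the probability-mass rule).
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(t < 0) or np.any(t != np.rint(t)):
        raise ValueError("counts must be non-negative integers")
    a, b = t[0]
    c, d = t[1]
    if b * c > 0:
        odds = (a * d) / (b * c)
    elif a * d > 0:
        odds = np.inf
    else:
        odds = np.nan
    _, p = stats.fisher_exact(t.astype(int), alternative="two-sided")
    return float(odds), float(p)


def test_enrichment(deg_genes: set, universe: set, scan: pd.DataFrame) -> EnrichmentResult:
    """Fisher enrichment of CAG-run-containing transcripts among DEGs.

    ``scan`` is a per-gene table with columns gene and contains_run covering
    the universe; ``deg_genes`` must be a non-empty subset of ``universe``.
    """
    deg_genes, universe = set(deg_genes), set(universe)
    if not deg_genes:
        raise ValueError("empty DEG set gives a degenerate margin")
    if not deg_genes <= universe:
        raise ValueError("DEG genes must be a subset of the universe")
    flags = scan.set_index("gene")["contains_run"]
    missing = universe - set(flags.index)
    if missing:
        raise ValueError(f"scan missing {len(missing)} universe genes")
    cag = {g for g in universe if bool(flags[g])}
    a = len(deg_genes & cag)
    b = len(deg_genes - cag)
    c = len(cag - deg_genes)
    d = len(universe) - a - b - c
    table = np.array([[a, b], [c, d]])
    odds, p = fisher_exact_2x2(table)
    return EnrichmentResult(table=table, odds_ratio=odds, p_two_sided=p)
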