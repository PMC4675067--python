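"""Synonymous / nonsynonymous substitution rates by Nei-Gojobori counting.

Sites: at each codon position, the synonymous fraction is the share of the
three possible nucleotide changes that preserve the amino acid; changes that
create a stop codon count as nonsynonymous.  Site counts are averaged over
the two sequences.  Differences: codons differing at k positions are scored
over all k! mutational pathways, averaging the synonymous/nonsynonymous step
counts (steps through stop codons count as nonsynonymous).  Proportions are
corrected with the Jukes-Cantor formula

    Ks = -(3/4) ln(1 - (4/3) ps),    Ka analogous,

which is undefined for ps or pn >= 3/4 (the estimate is then flagged
invalid).  This counting estimator is self-contained and hand-verifiable;
maximum-likelihood (codeml-style) parity is not promised.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from Bio.Data.CodonTable import standard_dna_table

from .model import InputError

_CODON_TO_AA: Dict[str, str] = dict(standard_dna_table.forward_table)
for _stop in standard_dna_table.stop_codons:
    _CODON_TO_AA[_stop] = "*"
_BASES = "ACGT"


@dataclass
class KsEstimate:
    Ks: float
    Ka: float
    S: float
    N: float
    Sd: float
    Nd: float
    valid: bool


def _check_codon(codon: str) -> str:
    codon = codon.upper()
    if codon not in _CODON_TO_AA:
        raise InputError(f"not an unambiguous codon: {codon!r}")
    if _CODON_TO_AA[codon] == "*":
        raise InputError(f"internal stop codon {codon!r}")
    return codon


def _syn_fraction(codon: str) -> float:
    """Sum over positions of the synonymous fraction of possible changes."""
    aa = _CODON_TO_AA[codon]
    s = 0.0
    for pos in range(3):
        syn = 0
        for base in _BASES:
            if base == codon[pos]:
                continue
            alt = codon[:pos] + base + codon[pos + 1 :]
            if _CODON_TO_AA[alt] == aa:  # stop codons never match -> nonsyn
                syn += 1
        s += syn / 3.0
    return s


def _pathway_diffs(c1: str, c2: str) -> Tuple[float, float]:
    """(synonymous, nonsynonymous) differences averaged over all pathways."""
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0
    total_s = 0.0
    total_n = 0.0
    n_paths = 0
    for order in permutations(diff_pos):
        cur = c1
        s = n = 0
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if (
                _CODON_TO_AA[cur] != "*"
                and _CODON_TO_AA[nxt] != "*"
                and _CODON_TO_AA[cur] == _CODON_TO_AA[nxt]
            ):
                s += 1
            else:
                n += 1
            cur = nxt
        total_s += s
        total_n += n
        n_paths += 1
    return total_s / n_paths, total_n / n_paths


def _jc_correct(p: float) -> float:
    return -0.75 * math.log(1.0 - (4.0 / 3.0) * p)


def ks_ng86(seq_a: str, seq_b: str) -> KsEstimate:
    """Nei-Gojobori Ks/Ka for a pair of aligned, gap-free codon sequences."""
    seq_a = seq_a.upper().replace("U", "T")
    seq_b = seq_b.upper().replace("U", "T")
    if len(seq_a) != len(seq_b):
        raise InputError(
            f"sequence lengths differ: {len(seq_a)} vs {len(seq_b)}"
        )
    if len(seq_a) % 3 != 0:
        raise InputError(f"sequence length {len(seq_a)} is not a multiple of 3")
    if not seq_a:
        raise InputError("empty sequences")

    S = 0.0
    Sd = 0.0
    Nd = 0.0
    n_codons = len(seq_a) // 3
    for i in range(n_codons):
        ca = _check_codon(seq_a[3 * i : 3 * i + 3])
        cb = _check_codon(seq_b[3 * i : 3 * i + 3])
        S += (_syn_fraction(ca) + _syn_fraction(cb)) / 2.0
        s, n = _pathway_diffs(ca, cb)
        Sd += s
        Nd += n
    N = 3.0 * n_codons - S

    ps = Sd / S if S > 0 else 0.0
    pn = Nd / N if N > 0 else 0.0
    valid = ps < 0.75 and pn < 0.75
    Ks = _jc_correct(ps) if valid else math.nan
    Ka = _jc_correct(pn) if valid else math.nan
    return KsEstimate(Ks=Ks, Ka=Ka, S=S, N=N, Sd=Sd, Nd=Nd, valid=valid)


def ks_by_pair_class(
    retentions: Iterable,
    sequences: Dict[str, str],
) -> Tuple[Dict[str, List[float]], int]:
    """Ks values per subgenome pair class (LF-MF1, LF-MF2, MF1-MF2, all).

    ``retentions`` are per-ancestral-gene retention records carrying
    ``copies`` as (label, extant_gene_id) pairs; triplets contribute one pair
    estimate to each of the three classes.  Returns (groups, n_invalid).
    """
    groups: Dict[str, List[float]] = {"LF-MF1": [], "LF-MF2": [], "MF1-MF2": [], "all": []}
    n_invalid = 0
    for ret in retentions:
        labeled = [
            (label, gid)
            for label, gid in ret.copies
            if label is not None and gid in sequences
        ]
        for i in range(len(labeled)):
            for j in range(i + 1, len(labeled)):
                (la, ga), (lb, gb) = labeled[i], labeled[j]
                if la == lb:
                    continue
                key = "-".join(sorted((la, lb), key=["LF", "MF1", "MF2"].index))
                est = ks_ng86(sequences[ga], sequences[gb])
                if not est.valid:
                    n_invalid += 1
                    continue
                groups.setdefault(key, []).append(est.Ks)
                groups["all"].append(est.Ks)
    return groups, n_invalid
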