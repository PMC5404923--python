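"""Counting-based dN/dS estimation (Nei-Gojobori 1986 style).

Synonymous and nonsynonymous *sites* are counted per codon as the
fraction of the three possible single-nucleotide changes at each position
that preserve the encoded amino acid (changes creating stop codons count
as nonsynonymous, so every codon contributes exactly three sites); site
totals are averaged over the two sequences.  *Differences* between a
codon pair are averaged over all minimal mutational pathways, discarding
pathways that pass through an intermediate stop codon (all pathways are
used if every one is blocked, with stop-involving steps counted as
nonsynonymous).  Proportions are corrected for multiple hits with the
Jukes-Cantor formula d = -(3/4) ln(1 - (4/3) p), undefined at p >= 3/4.

omega = dN/dS quantifies selective pressure: well below 1 indicates
purifying selection; drift toward 1 indicates its relaxation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from itertools import combinations, permutations
from typing import Iterable, Mapping

from Bio.Data import CodonTable

_TABLE = CodonTable.unambiguous_dna_by_id[1]
NUCLEOTIDES = "ACGT"
STOP_CODONS = frozenset(_TABLE.stop_codons)
CODON_TO_AA = dict(_TABLE.forward_table)
SENSE_CODONS = frozenset(CODON_TO_AA)


class DnDsError(ValueError):
    pass


@dataclass(frozen=True)
class OmegaEstimate:
    """Per-pair or per-clade substitution rates and their ratio.

    ``omega`` is None (undefined) when dS is zero, undefined through
    saturation, or when no informative pairs exist.
    """

    dN: float | None
    dS: float | None
    omega: float | None
    n_pairs: int

    @classmethod
    def from_rates(cls, dN: float, dS: float, n_pairs: int = 0
                   ) -> "OmegaEstimate":
        omega = dN / dS if dS and dS > 0 else None
        return cls(dN=dN, dS=dS, omega=omega, n_pairs=n_pairs)


@dataclass(frozen=True)
class CodonAlignment:
    """Equal-length codon sequences with gaps in whole triplets."""

    sequences: Mapping[str, str]

    def __post_init__(self) -> None:
        seqs = {t: s.upper() for t, s in dict(self.sequences).items()}
        object.__setattr__(self, "sequences", seqs)
        lengths = {len(s) for s in seqs.values()}
        if len(lengths) > 1:
            raise DnDsError("alignment rows differ in length")
        if lengths and next(iter(lengths)) % 3:
            raise DnDsError("alignment length not divisible by 3")
        for taxon, s in seqs.items():
            for i in range(0, len(s), 3):
                codon = s[i:i + 3]
                if "-" in codon and codon != "---":
                    raise DnDsError(
                        f"taxon {taxon!r}: gap not codon-aligned at {i}")
                if codon in STOP_CODONS:
                    raise DnDsError(
                        f"taxon {taxon!r}: internal stop codon at {i}")

    @property
    def taxa(self) -> list[str]:
        return sorted(self.sequences)

    def codons(self, taxon: str) -> list[str]:
        s = self.sequences[taxon]
        return [s[i:i + 3] for i in range(0, len(s), 3)]


def synonymous_sites(codon: str) -> Fraction:
    """Synonymous site count of a sense codon (0..3, exact rational)."""
    aa = CODON_TO_AA[codon]
    syn = 0
    for pos in range(3):
        for nt in NUCLEOTIDES:
            if nt == codon[pos]:
                continue
            alt = codon[:pos] + nt + codon[pos + 1:]
            if alt in SENSE_CODONS and CODON_TO_AA[alt] == aa:
                syn += 1
    return Fraction(syn, 3)


_SYN_SITES = {c: synonymous_sites(c) for c in SENSE_CODONS}


def _step_is_synonymous(before: str, after: str) -> bool:
    if before in STOP_CODONS or after in STOP_CODONS:
        return False
    return CODON_TO_AA[before] == CODON_TO_AA[after]


def pathway_differences(a: str, b: str) -> tuple[Fraction, Fraction]:
    """(synonymous, nonsynonymous) differences between two sense codons,
    averaged over minimal mutational pathways."""
    diff = [i for i in range(3) if a[i] != b[i]]
    if not diff:
        return Fraction(0), Fraction(0)
    paths = []
    for order in permutations(diff):
        current = a
        steps = []
        blocked = False
        for pos in order:
            nxt = current[:pos] + b[pos] + current[pos + 1:]
            steps.append((current, nxt))
            if nxt in STOP_CODONS and nxt != b:
                blocked = True
            current = nxt
        paths.append((blocked, steps))
    usable = [steps for blocked, steps in paths if not blocked]
    if not usable:
        usable = [steps for _, steps in paths]
    syn = Fraction(0)
    non = Fraction(0)
    for steps in usable:
        for before, after in steps:
            if _step_is_synonymous(before, after):
                syn += 1
            else:
                non += 1
    n = len(usable)
    return syn / n, non / n


def jukes_cantor(p: float) -> float | None:
    """Multiple-hit correction; None when saturated (p >= 3/4)."""
    if p < 0:
        raise DnDsError(f"negative proportion {p}")
    if p >= 0.75:
        return None
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def _is_sense(codon: str) -> bool:
    return codon in SENSE_CODONS


def ng86_pairwise(a: str, b: str) -> OmegaEstimate:
    """NG86 dN/dS between two aligned codon sequences.

    Codon columns containing a gap or an ambiguous base in either sequence
    are dropped pairwise.  Internal stop codons are rejected.
    """
    a, b = a.upper(), b.upper()
    if len(a) != len(b):
        raise DnDsError(f"length mismatch: {len(a)} vs {len(b)}")
    if len(a) % 3:
        raise DnDsError("sequence length not divisible by 3")
    S = Fraction(0)
    Sd = Fraction(0)
    Nd = Fraction(0)
    n_codons = 0
    for i in range(0, len(a), 3):
        ca, cb = a[i:i + 3], b[i:i + 3]
        if "-" in ca or "-" in cb:
            continue
        for c, taxon in ((ca, "first"), (cb, "second")):
            if c in STOP_CODONS and i + 3 < len(a):
                raise DnDsError(
                    f"internal stop codon in {taxon} sequence at {i}")
        if not (_is_sense(ca) and _is_sense(cb)):
            continue  # terminal stop or ambiguous base: drop the column
        n_codons += 1
        S += (_SYN_SITES[ca] + _SYN_SITES[cb]) / 2
        ds, dn = pathway_differences(ca, cb)
        Sd += ds
        Nd += dn
    if n_codons == 0:
        return OmegaEstimate(dN=None, dS=None, omega=None, n_pairs=0)
    N = 3 * n_codons - S
    pS = float(Sd / S) if S > 0 else 0.0
    pN = float(Nd / N) if N > 0 else 0.0
    dS = jukes_cantor(pS)
    dN = jukes_cantor(pN)
    omega = None
    if dN is not None and dS is not None and dS > 0:
        omega = dN / dS
    return OmegaEstimate(dN=dN, dS=dS, omega=omega, n_pairs=1)


def clade_omega(alignment: CodonAlignment, clade_leaves: Iterable[str]
                ) -> OmegaEstimate:
    """Mean pairwise dN and dS over all within-clade pairs.

    omega is the ratio of mean rates (not the mean of ratios), which stays
    stable when some pairwise dS is near zero.  Pairs with saturated
    (undefined) rates are dropped.
    """
    leaves = sorted(set(clade_leaves))
    missing = [t for t in leaves if t not in alignment.sequences]
    if missing:
        raise DnDsError(f"clade leaves absent from alignment: {missing}")
    if len(leaves) < 2:
        raise DnDsError("a clade needs at least two leaves")
    dns, dss = [], []
    for x, y in combinations(leaves, 2):
        est = ng86_pairwise(alignment.sequences[x], alignment.sequences[y])
        if est.dN is not None and est.dS is not None:
            dns.append(est.dN)
            dss.append(est.dS)
    if not dns:
        return OmegaEstimate(dN=None, dS=None, omega=None, n_pairs=0)
    mean_dn = sum(dns) / len(dns)
    mean_ds = sum(dss) / len(dss)
    omega = mean_dn / mean_ds if mean_ds > 0 else None
    return OmegaEstimate(dN=mean_dn, dS=mean_ds, omega=omega,
                         n_pairs=len(dns))
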