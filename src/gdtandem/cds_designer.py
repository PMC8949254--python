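"""Reverse translation of designed proteins into expression-ready DNA.

Tandem-repeat coding sequences are genetically unstable: long perfect direct
repeats recombine in vivo.  The designer therefore (1) restricts itself to
codons preferred in E. coli, (2) samples alternative synonymous codons for
Ser/Thr/Leu to break up repeats, (3) keeps enzyme recognition sites used for
cloning out of module interiors, (4) supports an A/C-only nucleotide alphabet
for the translation-initiation region, and (5) splits the final duplex into
annealing oligonucleotides no longer than the synthesis limit (63 nt).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio.Seq import Seq

__all__ = [
    "CodonTable",
    "ECOLI_K12",
    "DesignConstraints",
    "InfeasibleCodonError",
    "reverse_translate",
    "translate",
    "longest_direct_repeat",
    "scan_restriction_sites",
    "OligoPair",
    "split_oligos",
    "gc_content",
]


# ---------------------------------------------------------------------------
# Codon usage
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CodonTable:
    """Per-amino-acid synonymous codon usage fractions for one host."""

    host: str
    usage: Mapping[str, Mapping[str, float]]

    def __post_init__(self) -> None:
        for aa, codons in self.usage.items():
            if not codons:
                raise ValueError(f"no codons for {aa}")
            if any(f < 0 for f in codons.values()):
                raise ValueError(f"negative frequency for {aa}")

    def codons_by_frequency(self, aa: str) -> list[tuple[str, float]]:
        """Codons for ``aa``, most frequent first (alphabetical tie-break)."""
        items = sorted(self.usage[aa].items(), key=lambda kv: (-kv[1], kv[0]))
        return items


#: E. coli K-12 codon usage fractions (standard-strain usage table).
ECOLI_K12 = CodonTable(
    host="E. coli K-12",
    usage={
        "A": {"GCG": 0.36, "GCC": 0.27, "GCA": 0.21, "GCT": 0.16},
        "R": {"CGT": 0.38, "CGC": 0.40, "CGG": 0.10, "CGA": 0.06,
              "AGA": 0.04, "AGG": 0.02},
        "N": {"AAC": 0.55, "AAT": 0.45},
        "D": {"GAT": 0.63, "GAC": 0.37},
        "C": {"TGC": 0.56, "TGT": 0.44},
        "Q": {"CAG": 0.65, "CAA": 0.35},
        "E": {"GAA": 0.69, "GAG": 0.31},
        "G": {"GGC": 0.40, "GGT": 0.34, "GGG": 0.15, "GGA": 0.11},
        "H": {"CAT": 0.57, "CAC": 0.43},
        "I": {"ATT": 0.51, "ATC": 0.42, "ATA": 0.07},
        "L": {"CTG": 0.50, "TTA": 0.13, "TTG": 0.13, "CTT": 0.10,
              "CTC": 0.10, "CTA": 0.04},
        "K": {"AAA": 0.77, "AAG": 0.23},
        "M": {"ATG": 1.0},
        "F": {"TTT": 0.57, "TTC": 0.43},
        "P": {"CCG": 0.52, "CCA": 0.19, "CCT": 0.16, "CCC": 0.12},
        "S": {"AGC": 0.28, "TCT": 0.15, "TCG": 0.15, "AGT": 0.15,
              "TCC": 0.15, "TCA": 0.12},
        "T": {"ACC": 0.44, "ACG": 0.27, "ACT": 0.17, "ACA": 0.13},
        "W": {"TGG": 1.0},
        "Y": {"TAT": 0.57, "TAC": 0.43},
        "V": {"GTG": 0.37, "GTT": 0.26, "GTC": 0.20, "GTA": 0.15},
    },
)

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def revcomp(dna: str) -> str:
    return dna.translate(_COMPLEMENT)[::-1]


def translate(dna: str) -> str:
    """Standard-code translation of a CDS (no stop handling)."""
    return str(Seq(dna).translate())


def gc_content(dna: str) -> float:
    if not dna:
        return 0.0
    return (dna.count("G") + dna.count("C")) / len(dna)


# ---------------------------------------------------------------------------
# Constraints
# ---------------------------------------------------------------------------

class InfeasibleCodonError(ValueError):
    """No codon satisfies the alphabet/forbidden-site constraints."""


@dataclass
class DesignConstraints:
    """Knobs for constrained reverse translation.

    ``diversify_residues`` are residues whose synonymous codons are sampled
    (frequency-weighted among codons with usage >= ``diversify_min_freq``) to
    break direct repeats; the remaining residues always take the most frequent
    compatible codon.
    """

    allowed_nucleotides: frozenset[str] = frozenset("ACGT")
    forbidden_sites: tuple[str, ...] = ()
    diversify_residues: frozenset[str] = frozenset("STL")
    diversify: bool = True
    diversify_min_freq: float = 0.1
    max_repeat_len: int = 12
    gc_window: tuple[float, float, int] = (0.3, 0.7, 100)  # advisory only
    rng_seed: int = 0
    max_iterations: int = 500

    def __post_init__(self) -> None:
        self.allowed_nucleotides = frozenset(self.allowed_nucleotides)
        self.diversify_residues = frozenset(self.diversify_residues)
        self.forbidden_sites = tuple(s.upper() for s in self.forbidden_sites)
        if not self.allowed_nucleotides:
            raise ValueError("allowed_nucleotides must be non-empty")
        if self.max_repeat_len < 8:
            raise ValueError("max_repeat_len must be >= 8")


def _compatible_codons(
    aa: str, table: CodonTable, constraints: DesignConstraints
) -> list[tuple[str, float]]:
    allowed = constraints.allowed_nucleotides
    out = [
        (codon, freq)
        for codon, freq in table.codons_by_frequency(aa)
        if set(codon) <= allowed
    ]
    if not out:
        raise InfeasibleCodonError(
            f"residue {aa!r}: no codon within alphabet "
            f"{{{','.join(sorted(allowed))}}}"
        )
    return out


def _forbidden_hits(dna: str, sites: Sequence[str]) -> list[tuple[int, int]]:
    """(start, end) spans of forbidden sites on either strand."""
    hits = []
    for site in sites:
        for probe in {site, revcomp(site)}:
            start = 0
            while True:
                idx = dna.find(probe, start)
                if idx < 0:
                    break
                hits.append((idx, idx + len(probe)))
                start = idx + 1
    return hits


def reverse_translate(
    aa_sequence: str,
    codon_table: CodonTable = ECOLI_K12,
    constraints: DesignConstraints | None = None,
) -> str:
    """Reverse-translate a protein into a CDS under the design constraints.

    Deterministic for a fixed ``constraints.rng_seed``.  The returned CDS
    translates back to the input exactly, contains no forbidden site on
    either strand, and — when diversification is on — has had codons at the
    midpoints of over-long direct repeats greedily resampled.
    """
    constraints = constraints or DesignConstraints()
    aa_sequence = aa_sequence.upper()
    rng = np.random.default_rng(constraints.rng_seed)

    options = {aa: _compatible_codons(aa, codon_table, constraints)
               for aa in set(aa_sequence)}

    def pick(aa: str, exclude: str | None = None) -> str:
        opts = options[aa]
        if constraints.diversify and aa in constraints.diversify_residues:
            pool = [(c, f) for c, f in opts
                    if f >= constraints.diversify_min_freq and c != exclude]
            if not pool:
                pool = [(c, f) for c, f in opts if c != exclude] or opts
            codons, freqs = zip(*pool)
            p = np.asarray(freqs, dtype=float)
            return str(codons[rng.choice(len(codons), p=p / p.sum())])
        for c, _ in opts:
            if c != exclude:
                return c
        return opts[0][0]

    codons = [pick(aa) for aa in aa_sequence]

    def resample_at(codon_idx: int) -> bool:
        aa = aa_sequence[codon_idx]
        if len(options[aa]) < 2:
            return False
        old = codons[codon_idx]
        if constraints.diversify and aa in constraints.diversify_residues:
            codons[codon_idx] = pick(aa, exclude=old)
        else:
            alts = [c for c, _ in options[aa] if c != old]
            codons[codon_idx] = alts[int(rng.integers(len(alts)))]
        return codons[codon_idx] != old

    # Iteratively repair forbidden sites and over-long repeats.
    for _ in range(constraints.max_iterations):
        dna = "".join(codons)
        hits = _forbidden_hits(dna, constraints.forbidden_sites)
        if hits:
            start, end = hits[0]
            span = range(start // 3, (end - 1) // 3 + 1)
            changeable = [i for i in span if len(options[aa_sequence[i]]) > 1]
            if not changeable:
                raise InfeasibleCodonError(
                    f"forbidden site {dna[start:end]!r} at {start} cannot be "
                    "removed: all overlapping residues are single-codon"
                )
            resample_at(changeable[int(rng.integers(len(changeable)))])
            continue
        if constraints.diversify:
            rep_len, positions = longest_direct_repeat(dna)
            if rep_len > constraints.max_repeat_len:
                mid = positions[0] + rep_len // 2
                span = [i for i in range(max(0, positions[0] // 3),
                                         (positions[0] + rep_len - 1) // 3 + 1)]
                # prefer the midpoint codon, fall back to any codon in the span
                candidates = sorted(span, key=lambda i: abs(i - mid // 3))
                if any(resample_at(i) for i in candidates):
                    continue
        break

    dna = "".join(codons)
    if _forbidden_hits(dna, constraints.forbidden_sites):
        raise InfeasibleCodonError("could not eliminate forbidden sites")
    lo, hi, win = constraints.gc_window
    if len(dna) >= win:
        gcs = [gc_content(dna[i:i + win]) for i in range(0, len(dna) - win + 1, win)]
        if min(gcs) < lo or max(gcs) > hi:
            warnings.warn(
                f"GC content outside [{lo:.0%}, {hi:.0%}] in a {win} nt window"
            )
    assert translate(dna) == aa_sequence
    return dna


# ---------------------------------------------------------------------------
# Direct-repeat scoring (suffix array + LCP)
# ---------------------------------------------------------------------------

def longest_direct_repeat(dna: str) -> tuple[int, tuple[int, int]]:
    """Length and start positions of the longest same-strand direct repeat.

    A direct repeat is a substring occurring at two or more distinct start
    positions (overlap allowed).  Returns ``(0, (-1, -1))`` when every
    character is unique.  Implemented with a sorted suffix array and Kasai's
    adjacent-LCP argument: the longest repeated substring is the maximal
    common prefix of two lexicographically adjacent suffixes.
    """
    n = len(dna)
    if n < 2:
        return 0, (-1, -1)
    data = dna.encode()
    order = sorted(range(n), key=lambda i: data[i:])
    rank = [0] * n
    for r, i in enumerate(order):
        rank[i] = r
    best, where = 0, (-1, -1)
    h = 0  # Kasai: LCP with previous-ranked suffix, decreases by <=1 per step
    for i in range(n):
        if rank[i] == 0:
            h = 0
            continue
        j = order[rank[i] - 1]
        while i + h < n and j + h < n and dna[i + h] == dna[j + h]:
            h += 1
        if h > best:
            best, where = h, (min(i, j), max(i, j))
        if h:
            h -= 1
    return best, where


# ---------------------------------------------------------------------------
# Restriction-site scan
# ---------------------------------------------------------------------------

def scan_restriction_sites(
    dna: str,
    enzymes: Mapping[str, str] | Iterable,
) -> list[tuple[str, int, str]]:
    """All recognition-site occurrences as (enzyme, position, strand).

    ``enzymes`` maps names to recognition strings, or is an iterable of
    objects with ``name``/``recognition`` attributes.  Positions are 0-based
    top-strand coordinates of the site start; palindromic sites are reported
    once with strand "+".
    """
    if not isinstance(enzymes, Mapping):
        enzymes = {e.name: e.recognition for e in enzymes}
    hits = []
    for name, site in enzymes.items():
        site = site.upper()
        rc = revcomp(site)
        probes = [(site, "+")] if rc == site else [(site, "+"), (rc, "-")]
        for probe, strand in probes:
            start = 0
            while True:
                idx = dna.find(probe, start)
                if idx < 0:
                    break
                hits.append((name, idx, strand))
                start = idx + 1
    return sorted(hits, key=lambda h: (h[1], h[0]))


# ---------------------------------------------------------------------------
# Oligo splitting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OligoPair:
    """One ordered synthesis oligo: name, sequence (5'->3'), strand, start."""

    name: str
    sequence: str
    strand: str  # "top" | "bottom"
    position: int  # 0-based start on the top strand


def split_oligos(
    dna: str, max_len: int = 63, overlap: int = 12
) -> list[OligoPair]:
    """Split a duplex into annealing oligos within the synthesis length cap.

    Top-strand oligos tile the sequence end to end (their concatenation
    reconstructs the input); bottom-strand oligos are reverse complements of
    windows shifted by ``overlap``, so that every junction on one strand is
    bridged by ``overlap`` paired nucleotides on the other.
    """
    if max_len < 2 * overlap:
        raise ValueError("max_len must be >= 2*overlap for staggered assembly")
    n = len(dna)
    if n == 0:
        return []
    if n <= max_len:  # single duplex: one oligo per strand
        return [
            OligoPair("top_1", dna, "top", 0),
            OligoPair("bottom_1", revcomp(dna), "bottom", 0),
        ]
    # top segments no longer than max_len - overlap, so that bottom windows
    # (shifted right by `overlap`) also respect the synthesis cap
    eff = max_len - overlap
    n_top = -(-n // eff)  # ceil
    step = -(-n // n_top)
    top_cuts = list(range(0, n, step)) + [n]

    oligos: list[OligoPair] = []
    for k in range(len(top_cuts) - 1):
        a, b = top_cuts[k], top_cuts[k + 1]
        oligos.append(OligoPair(f"top_{k + 1}", dna[a:b], "top", a))
    bottom_cuts = sorted(
        {0, n} | {min(c + overlap, n) for c in top_cuts[1:-1]}
    )
    for k in range(len(bottom_cuts) - 1):
        a, b = bottom_cuts[k], bottom_cuts[k + 1]
        if b - a > max_len:
            raise ValueError("infeasible overlap geometry for this length")
        oligos.append(OligoPair(f"bottom_{k + 1}", revcomp(dna[a:b]), "bottom", a))
    return oligos
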