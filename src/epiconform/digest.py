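"""In-silico tryptic digestion, peptide masses, observable-peptide
counting and paralog isobaric-discriminant discovery.

Trypsin cleaves C-terminal to K or R; with the proline rule on
(default), K/R-P bonds are not cleaved, matching common search-engine
defaults.  Peptide coordinates are 1-based inclusive.  Masses are
neutral (uncharged) peptide masses from pyteomics' standard residue
tables; the "Mr 700-2800" observable window is interpreted as neutral
monoisotopic mass with inclusive bounds, consistent with the
monoisotopic masses used for XIC quantitation.  N-terminal Met removal
and modified termini are deliberately not modelled for counting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from pyteomics import mass as _ptmass

from epiconform.io import CANONICAL_AA, SequenceRecord


@dataclass(frozen=True)
class DigestParams:
    """Digestion and observable-window parameters.

    Defaults match standard spectral-counting practice: trypsin, zero
    missed cleavages, neutral monoisotopic Mr window 700-2800 Da.
    """

    enzyme: str = "trypsin"
    max_miscleavages: int = 0
    proline_rule: bool = True
    mass_type: str = "monoisotopic"  # or "average"
    mr_min: float = 700.0
    mr_max: float = 2800.0

    def __post_init__(self) -> None:
        if self.enzyme != "trypsin":
            raise ValueError("only trypsin is supported")
        if self.max_miscleavages < 0:
            raise ValueError("max_miscleavages must be >= 0")
        if self.mass_type not in ("monoisotopic", "average"):
            raise ValueError("mass_type must be monoisotopic or average")
        if not self.mr_min < self.mr_max:
            raise ValueError("mr_min must be < mr_max")


@dataclass(frozen=True)
class Peptide:
    """A proteolytic fragment with 1-based inclusive coordinates."""

    sequence: str
    start: int
    end: int
    miscleavages: int
    mass: float

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class IsobaricDiscriminant:
    """A cross-paralog peptide pair of (near-)equal mass but different
    sequence, usable to discriminate the paralogs in MS data."""

    parent_a: str
    parent_b: str
    peptide_a: Peptide
    peptide_b: Peptide
    shared_mass: float
    mass_difference_ppm: float
    differing_positions: tuple[tuple[int, str, str], ...]


def peptide_mass(sequence: str, mass_type: str = "monoisotopic") -> float:
    """Neutral peptide mass in Da: sum of residue masses plus one water."""
    if not sequence:
        raise ValueError("empty peptide sequence")
    bad = set(sequence) - CANONICAL_AA
    if bad:
        raise ValueError(f"non-canonical residue letters {sorted(bad)}")
    if mass_type == "monoisotopic":
        return _ptmass.fast_mass(sequence)
    if mass_type == "average":
        return _ptmass.calculate_mass(sequence=sequence, average=True)
    raise ValueError(f"unknown mass_type {mass_type!r}")


def cleavage_sites(residues: str, proline_rule: bool = True) -> list[int]:
    """0-based positions i such that the bond after residues[i] is cleaved."""
    sites = []
    n = len(residues)
    for i, aa in enumerate(residues):
        if aa in "KR" and i < n - 1:
            if proline_rule and residues[i + 1] == "P":
                continue
            sites.append(i)
    return sites


def digest(seq: SequenceRecord, params: DigestParams = DigestParams()) -> list[Peptide]:
    """Tryptic digestion of a protein sequence.

    Returns every fragment with 0..max_miscleavages internal missed
    cleavage sites, terminal fragments included, ordered by start then
    length.  The 0-miscleavage fragments partition the input sequence.
    """
    residues = seq.residues
    if not residues:
        raise ValueError("empty sequence")
    sites = cleavage_sites(residues, params.proline_rule)
    # boundaries are 0-based start offsets of each 0-miscleavage fragment
    starts = [0] + [s + 1 for s in sites]
    ends = [s + 1 for s in sites] + [len(residues)]  # exclusive
    peptides = []
    n_frag = len(starts)
    for i in range(n_frag):
        for k in range(params.max_miscleavages + 1):
            j = i + k
            if j >= n_frag:
                break
            s, e = starts[i], ends[j]
            sub = residues[s:e]
            peptides.append(Peptide(
                sequence=sub, start=s + 1, end=e, miscleavages=k,
                mass=peptide_mass(sub, params.mass_type),
            ))
    peptides.sort(key=lambda p: (p.start, p.end))
    return peptides


def count_observable_peptides(seq: SequenceRecord,
                              params: DigestParams = DigestParams()) -> int:
    """Number of distinct observable tryptic peptides (N_obsbl).

    Counts 0-miscleavage peptides whose neutral mass lies inside the
    inclusive [mr_min, mr_max] window; duplicate sequences from repeats
    are counted once.
    """
    zero = DigestParams(enzyme=params.enzyme, max_miscleavages=0,
                        proline_rule=params.proline_rule,
                        mass_type=params.mass_type,
                        mr_min=params.mr_min, mr_max=params.mr_max)
    seen = {
        p.sequence for p in digest(seq, zero)
        if params.mr_min <= p.mass <= params.mr_max
    }
    return len(seen)


def find_isobaric_discriminants(seq_a: SequenceRecord, seq_b: SequenceRecord,
                                params: DigestParams = DigestParams(),
                                ppm_tol: float = 0.0) -> list[IsobaricDiscriminant]:
    """All cross-paralog tryptic peptide pairs of matching mass but
    differing sequence.

    ``ppm_tol = 0`` (default) demands exact composition match — the
    Ile/Leu case has a mass difference of exactly zero.  Pairs with
    identical sequences are excluded: they cannot discriminate the
    paralogs.  Equal-length pairs are annotated with their differing
    positions (1-based offset within the peptide).
    """
    if ppm_tol < 0:
        raise ValueError("ppm_tol must be >= 0")
    pep_a = _distinct(digest(seq_a, params))
    pep_b = _distinct(digest(seq_b, params))
    out = []
    for pa in pep_a:
        for pb in pep_b:
            if pa.sequence == pb.sequence:
                continue
            dm = abs(pa.mass - pb.mass)
            ppm = dm / pa.mass * 1e6
            if ppm > ppm_tol + 1e-9:
                continue
            diffs: tuple[tuple[int, str, str], ...] = ()
            if len(pa.sequence) == len(pb.sequence):
                diffs = tuple(
                    (off + 1, x, y)
                    for off, (x, y) in enumerate(zip(pa.sequence, pb.sequence))
                    if x != y
                )
            out.append(IsobaricDiscriminant(
                parent_a=seq_a.id, parent_b=seq_b.id,
                peptide_a=pa, peptide_b=pb,
                shared_mass=(pa.mass + pb.mass) / 2.0,
                mass_difference_ppm=ppm,
                differing_positions=diffs,
            ))
    out.sort(key=lambda d: (d.peptide_a.start, d.peptide_b.start))
    return out


def _distinct(peptides: list[Peptide]) -> list[Peptide]:
    seen: dict[str, Peptide] = {}
    for p in peptides:
        seen.setdefault(p.sequence, p)
    return list(seen.values())
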