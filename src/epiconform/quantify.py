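"""Identification filtering, phosphosite label-free quantitation,
spectral-counting abundance index and isoform ratios.

Search-engine identifications are filtered with the acceptance
thresholds of the original study, with the strictness of each
inequality preserved exactly: protein score >= 22, protein discriminant
score >= 0.0, peptide expectation value <= 0.01, phosphosite SLIP score
strictly > 6, cross-link peptide score strictly > 20, cross-link FDR
strictly < 5%, mass accuracy strictly < 10 ppm.

Phosphosite quantitation sums XIC intensities of all phosphopeptide
forms (charge states and miscleavage variants are distinct
measurements) per site, and condition ratios are normalized for protein
loading by an isoform-specific reference tryptic peptide.  Protein
abundance is estimated semi-quantitatively as the protein abundance
index PAI = N_obsd / N_obsbl (detected over theoretically observable
tryptic peptides).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from epiconform.io import IdentificationRecord


@dataclass(frozen=True)
class ThresholdSet:
    """Identification acceptance thresholds.

    The comparison direction and strictness of every criterion is fixed
    here, in one place, so audits are trivial:

    ==================  =========  ==========
    criterion           threshold  rule
    ==================  =========  ==========
    protein_score       22         >= (pass)
    discriminant        0.0        >=
    expectation         0.01       <=
    slip (phospho)      6          >  (strict)
    xl_score            20         >  (strict)
    fdr                 0.05       <  (strict)
    mass_error_ppm      10         <  (strict, on |error|)
    ==================  =========  ==========
    """

    protein_score_min: float = 22.0
    discriminant_min: float = 0.0
    expectation_max: float = 0.01
    slip_min: float = 6.0
    xl_score_min: float = 20.0
    fdr_max: float = 0.05
    mass_error_ppm_max: float = 10.0

    def __post_init__(self) -> None:
        for name in ("protein_score_min", "expectation_max", "slip_min",
                     "xl_score_min", "fdr_max", "mass_error_ppm_max"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class PhosphositeQuant:
    """Summed XIC intensity per (protein, phosphosite, condition)."""

    protein_id: str
    site: int           # 1-based protein residue index
    residue: str        # residue letter, e.g. "S"
    condition: str
    summed_intensity: float
    n_measurements: int  # distinct (sequence, charge, miscleavage) forms

    def __post_init__(self) -> None:
        if self.summed_intensity < 0:
            raise ValueError("summed_intensity must be >= 0")
        if self.summed_intensity > 0 and self.n_measurements < 1:
            raise ValueError("positive intensity requires >= 1 measurement")


@dataclass(frozen=True)
class PAIRecord:
    """Protein abundance index: detected over observable peptide counts."""

    protein_id: str
    n_obsd: int
    n_obsbl: int
    pai: float


# criteria evaluated in a fixed, documented order; a record's rejection
# is tallied against the first failing criterion
_CRITERIA = (
    ("protein_score",
     lambda r, t: r.protein_score is None or r.protein_score >= t.protein_score_min,
     ("protein",)),
    ("discriminant_score",
     lambda r, t: r.discriminant_score is None or r.discriminant_score >= t.discriminant_min,
     ("protein",)),
    ("expectation",
     lambda r, t: r.expectation is None or r.expectation <= t.expectation_max,
     ("protein", "peptide", "phosphopeptide")),
    ("slip_score",
     lambda r, t: r.slip_score is not None and r.slip_score > t.slip_min,
     ("phosphopeptide",)),
    ("xl_score",
     lambda r, t: r.xl_score is not None and r.xl_score > t.xl_score_min,
     ("crosslink",)),
    ("fdr",
     lambda r, t: r.fdr is not None and r.fdr < t.fdr_max,
     ("crosslink",)),
    ("mass_error_ppm",
     lambda r, t: r.mass_error_ppm is None or abs(r.mass_error_ppm) < t.mass_error_ppm_max,
     ("peptide", "phosphopeptide", "crosslink")),
)


def filter_identifications(records: Sequence[IdentificationRecord],
                           thresholds: ThresholdSet = ThresholdSet()
                           ) -> tuple[list[IdentificationRecord], dict[str, int]]:
    """Apply every class-appropriate threshold to each record.

    Returns the passing records (a subset of the input, order
    preserved) and a per-criterion rejection tally; each rejected
    record counts once, against the first criterion it fails in the
    documented order, so passes plus tallies partition the input.
    """
    passed: list[IdentificationRecord] = []
    rejected: dict[str, int] = {name: 0 for name, _f, _c in _CRITERIA}
    for rec in records:
        _require_class_fields(rec)
        for name, check, classes in _CRITERIA:
            if rec.record_class in classes and not check(rec, thresholds):
                rejected[name] += 1
                break
        else:
            passed.append(rec)
    return passed, rejected


def _require_class_fields(rec: IdentificationRecord) -> None:
    required = {
        "protein": ("protein_score", "discriminant_score", "expectation"),
        "peptide": ("expectation",),
        "phosphopeptide": ("expectation", "slip_score"),
        "crosslink": ("xl_score", "fdr", "mass_error_ppm"),
    }[rec.record_class]
    for name in required:
        if getattr(rec, name) is None:
            raise ValueError(
                f"{rec.record_class} record {rec.peptide_sequence!r} "
                f"missing required field {name!r}"
            )


def aggregate_phosphosite(records: Sequence[IdentificationRecord],
                          site_kinds: tuple[str, ...] = ("phospho",)
                          ) -> list[PhosphositeQuant]:
    """Sum phosphopeptide intensities per (protein, site, condition).

    Every phosphopeptide form — distinct (sequence, charge,
    miscleavage) combination — is a separate measurement whose
    intensity contributes to each localized site it carries.  A
    phosphopeptide record without a localized phospho site is an error.
    """
    sums: dict[tuple[str, int, str, str], float] = {}
    forms: dict[tuple[str, int, str, str], set] = {}
    for rec in records:
        if rec.record_class != "phosphopeptide":
            continue
        sites = [(site, kind) for site, kind in rec.modifications
                 if kind in site_kinds]
        if not sites:
            raise ValueError(
                f"phosphopeptide {rec.peptide_sequence!r} has no localized "
                f"phospho site"
            )
        for site, _kind in sites:
            key = (rec.protein_id, site, "S", rec.condition)
            sums[key] = sums.get(key, 0.0) + rec.intensity
            forms.setdefault(key, set()).add(
                (rec.peptide_sequence, rec.charge, rec.miscleavages))
    return [
        PhosphositeQuant(protein_id=pid, site=site, residue=res,
                         condition=cond, summed_intensity=total,
                         n_measurements=len(forms[(pid, site, res, cond)]))
        for (pid, site, res, cond), total in sorted(sums.items())
    ]


def normalized_ratio(phospho_num: float, phospho_den: float,
                     ref_num: float, ref_den: float
                     ) -> tuple[float, float, float, float]:
    """Loading-normalized phosphosite ratio between two conditions.

    raw_ratio        = phospho_num / phospho_den
    loading_ratio    = ref_num / ref_den   (reference tryptic peptide)
    normalized_ratio = raw_ratio / loading_ratio
    percent_change   = (normalized_ratio - 1) * 100

    All four intensities must be strictly positive.  Values are
    returned at full precision; rounding belongs to presentation.
    """
    for name, v in (("phospho_num", phospho_num), ("phospho_den", phospho_den),
                    ("ref_num", ref_num), ("ref_den", ref_den)):
        if not v > 0:
            raise ValueError(f"{name} must be > 0, got {v}")
    raw = phospho_num / phospho_den
    loading = ref_num / ref_den
    norm = raw / loading
    return raw, loading, norm, (norm - 1.0) * 100.0


def protein_abundance_index(protein_id: str, n_obsd: int,
                            n_obsbl: int) -> PAIRecord:
    """PAI = N_obsd / N_obsbl.

    N_obsd may exceed N_obsbl (miscleavage and modified forms are
    detected but not counted as observable); that case is permitted
    with a warning.
    """
    if n_obsbl <= 0:
        raise ValueError("n_obsbl must be > 0")
    if n_obsd < 0:
        raise ValueError("n_obsd must be >= 0")
    if n_obsd > n_obsbl:
        warnings.warn(
            f"{protein_id}: N_obsd ({n_obsd}) exceeds N_obsbl ({n_obsbl}); "
            "miscleavage/modification forms can inflate detected counts",
            stacklevel=2,
        )
    return PAIRecord(protein_id=protein_id, n_obsd=n_obsd, n_obsbl=n_obsbl,
                     pai=n_obsd / n_obsbl)


def isoform_ratio_from_counts(count_b: int, count_a: int) -> float:
    """Spectral-count isoform ratio count_b / count_a, half-up to 2 decimals."""
    if count_a <= 0:
        raise ValueError("denominator count must be > 0")
    if count_b < 0:
        raise ValueError("counts must be non-negative")
    ratio = count_b / count_a
    return math.floor(ratio * 100 + 0.5) / 100
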