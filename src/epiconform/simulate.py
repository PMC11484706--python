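"""Seeded synthetic-data generators with ground truth.

Every pipeline input class can be generated here with known truth, so
each analysis stage is testable without the original deposited raw
data.  The generators emulate the study's replicate design: three
replicates per condition, lognormal multiplicative intensity noise
(standard for MS peak heights; a coefficient of variation ``cv`` maps
to sigma_log = sqrt(ln(1 + cv^2))), planted condition effects on a
subset of residue pairs, reference-peptide loading factors, per-site
phosphorylation ratios, spectral-count rates per paralog, and Gaussian
Calpha trajectories with prescribed per-residue fluctuation amplitudes
and block correlation structure.

All generators are pure functions of their configuration (seed
included): identical inputs give identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from epiconform.crosslink import PairKey
from epiconform.digest import DigestParams, digest, peptide_mass
from epiconform.io import (
    CrosslinkSpeciesRecord,
    IdentificationRecord,
    SequenceRecord,
    Trajectory,
)


@dataclass
class SyntheticConfig:
    """Study-condition parameters for all generators.

    Defaults mirror the replicate design the pipeline targets: 50
    cross-linked pairs measured in 3 replicates per condition under
    10% lognormal intensity noise, with five pairs (all at sequence
    separation >= 8) carrying a planted 20-percentage-point %XL
    difference between conditions.
    """

    seed: int = 0
    # cross-link tables
    n_pairs: int = 50
    replicates: int = 3
    cv: float = 0.10
    conditions: tuple[str, str] = ("PU", "GA")
    n_planted: int = 5
    planted_delta: float = 20.0
    deadend_skew: float = 0.5   # fraction of dead-end signal on residue_i
    protein_id: str = "HSP90B_SYN"
    # quantitation tables
    quant_conditions: tuple[str, str] = ("ES", "Troph")
    loading_factors: dict | None = None        # condition -> factor
    true_site_ratios: dict | None = None       # site -> normalized ratio
    n_forms_per_site: int = 3
    n_decoys: int = 4
    # trajectory
    n_residues: int = 60
    n_frames: int = 500
    amplitudes: np.ndarray | None = None       # per-residue RMSF target (A)
    correlation_blocks: tuple = ((0, 20, 0.8),)  # (start, stop, rho), positional
    rigid_jitter: bool = False
    component_map: dict | None = None

    def __post_init__(self) -> None:
        if self.cv <= 0:
            raise ValueError("cv must be > 0")
        if not 0.0 < self.deadend_skew < 1.0:
            raise ValueError("deadend_skew must lie in (0, 1)")
        if self.n_planted > self.n_pairs:
            raise ValueError("more planted effects than pairs")
        for _s, _e, rho in self.correlation_blocks:
            if not 0.0 <= rho < 1.0:
                # the shared-factor construction realizes non-negative
                # equicorrelated blocks only
                raise ValueError("block correlations must lie in [0, 1)")
        if self.loading_factors is None:
            self.loading_factors = {self.quant_conditions[0]: 0.44,
                                    self.quant_conditions[1]: 1.0}
        if self.true_site_ratios is None:
            self.true_site_ratios = {255: 1.30, 226: 1.00}
        for factor in self.loading_factors.values():
            if factor <= 0:
                raise ValueError("loading factors must be > 0")


@dataclass
class GroundTruth:
    """Planted quantities the pipeline is expected to recover."""

    true_percent: dict | None = None       # (PairKey, condition) -> %XL
    true_outliers: set | None = None       # set of PairKey
    loading_factors: dict | None = None
    true_site_ratios: dict | None = None
    n_decoys: int = 0
    amplitudes: np.ndarray | None = None
    correlation: np.ndarray | None = None  # planted N x N DCCM target
    component_map: dict | None = None
    discriminant_peptides: list | None = None


def _sigma_log(cv: float) -> float:
    return math.sqrt(math.log(1.0 + cv * cv))


def _lognoise(rng: np.random.Generator, cv: float, size=None) -> np.ndarray:
    """Multiplicative lognormal noise with mean 1 and CV ``cv``."""
    s = _sigma_log(cv)
    return np.exp(rng.normal(-0.5 * s * s, s, size=size))


# ---------------------------------------------------------------------------
# cross-link species tables

def simulate_crosslink_tables(cfg: SyntheticConfig
                              ) -> tuple[list[CrosslinkSpeciesRecord], GroundTruth]:
    """Replicate cross-link/dead-end peak-height tables with planted effects.

    Pairs use disjoint residue pairs (no competing cross-links), so the
    expected %XL of a pair is exactly its configured truth: the
    cross-link peak height is drawn around T * p/100 and the two
    dead-end species split T * (1 - p/100) by ``deadend_skew``, each
    then perturbed by independent lognormal noise.  The first
    ``n_planted`` pairs (all at sequence separation >= 8) carry a
    ``planted_delta``-point higher %XL in the first condition.
    """
    rng = np.random.default_rng(cfg.seed)
    cond_hi, cond_lo = cfg.conditions
    pairs = []
    for k in range(cfg.n_pairs):
        start = 10 + 40 * k
        sep = 9 + int(rng.integers(0, 20)) if k % 7 else int(rng.integers(3, 8))
        pairs.append(PairKey(cfg.protein_id, start, start + sep))
    eligible = [p for p in pairs if p.seq_separation >= 8]
    planted = set(eligible[:cfg.n_planted])
    if len(planted) < cfg.n_planted:
        raise ValueError("not enough pairs with separation >= 8 to plant effects")

    truth_pct: dict[tuple[PairKey, str], float] = {}
    records: list[CrosslinkSpeciesRecord] = []
    for pair in pairs:
        base = float(rng.uniform(25.0, 55.0))
        truth_pct[(pair, cond_lo)] = base
        truth_pct[(pair, cond_hi)] = base + (cfg.planted_delta
                                             if pair in planted else 0.0)
        for cond in cfg.conditions:
            p = truth_pct[(pair, cond)] / 100.0
            if not 0.0 < p < 1.0:
                raise ValueError(f"target %XL outside (0, 100) for {pair}")
            for rep in range(1, cfg.replicates + 1):
                total = float(rng.lognormal(math.log(1e6), 0.3))
                ph_xl = total * p * float(_lognoise(rng, cfg.cv))
                de_total = total * (1.0 - p)
                ph_de_i = de_total * cfg.deadend_skew * float(_lognoise(rng, cfg.cv))
                ph_de_j = de_total * (1.0 - cfg.deadend_skew) \
                    * float(_lognoise(rng, cfg.cv))
                records.append(CrosslinkSpeciesRecord(
                    protein_id=pair.protein_id, species_type="crosslink",
                    residue_i=pair.residue_i, residue_j=pair.residue_j,
                    condition=cond, replicate=rep, peak_height=ph_xl))
                records.append(CrosslinkSpeciesRecord(
                    protein_id=pair.protein_id, species_type="deadend",
                    residue_i=pair.residue_i, condition=cond, replicate=rep,
                    peak_height=ph_de_i))
                records.append(CrosslinkSpeciesRecord(
                    protein_id=pair.protein_id, species_type="deadend",
                    residue_i=pair.residue_j, condition=cond, replicate=rep,
                    peak_height=ph_de_j))
    return records, GroundTruth(true_percent=truth_pct, true_outliers=planted)


# ---------------------------------------------------------------------------
# identification / intensity tables

def simulate_quant_tables(cfg: SyntheticConfig
                          ) -> tuple[list[IdentificationRecord], GroundTruth]:
    """Phosphopeptide + reference-peptide intensity tables with known truth.

    Reference-peptide intensities embed the configured loading factors;
    each phosphosite's summed intensity embeds loading x true site
    ratio, split over ``n_forms_per_site`` charge-state forms.  With
    ``cv -> 0`` the loading-normalized ratio recovers the truth
    exactly.  ``n_decoys`` phosphopeptide rows with boundary SLIP score
    (exactly 6, rejected by the strict rule) are appended with known
    count.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    cond_num, cond_den = cfg.quant_conditions
    protein = "HSP90B_SYN"
    records: list[IdentificationRecord] = []
    base_ref = 5e7
    for cond in cfg.quant_conditions:
        records.append(IdentificationRecord(
            peptide_sequence="ELISNASDALDK", protein_id=protein,
            record_class="peptide", condition=cond,
            expectation=1e-4, mass_error_ppm=1.0, charge=2,
            intensity=base_ref * cfg.loading_factors[cond]
            * float(_lognoise(rng, cfg.cv)),
        ))
    for site, ratio in sorted(cfg.true_site_ratios.items()):
        if ratio <= 0:
            raise ValueError("true site ratios must be > 0")
        base_site = float(rng.lognormal(math.log(2e6), 0.2))
        for cond in cfg.quant_conditions:
            scale = cfg.loading_factors[cond] * (ratio if cond == cond_num else 1.0)
            for form in range(cfg.n_forms_per_site):
                records.append(IdentificationRecord(
                    peptide_sequence=f"SYNPEPS{site}K", protein_id=protein,
                    record_class="phosphopeptide", condition=cond,
                    expectation=1e-3, slip_score=15.0, mass_error_ppm=2.0,
                    charge=2 + form, miscleavages=0,
                    modifications=((site, "phospho"),),
                    intensity=base_site * scale / cfg.n_forms_per_site
                    * float(_lognoise(rng, cfg.cv)),
                ))
    for d in range(cfg.n_decoys):
        records.append(IdentificationRecord(
            peptide_sequence=f"DECOYPEP{d}K", protein_id=protein,
            record_class="phosphopeptide", condition=cond_num,
            expectation=1e-3, slip_score=6.0, mass_error_ppm=2.0,
            charge=2, modifications=((999 + d, "phospho"),),
            intensity=float(rng.lognormal(math.log(1e5), 0.2)),
        ))
    return records, GroundTruth(loading_factors=dict(cfg.loading_factors),
                                true_site_ratios=dict(cfg.true_site_ratios),
                                n_decoys=cfg.n_decoys)


def simulate_spectral_counts(seed: int, rate_b: float, rate_a: float,
                             ) -> tuple[int, int]:
    """Poisson spectral counts for two paralogs with given expected rates."""
    if rate_a <= 0 or rate_b <= 0:
        raise ValueError("rates must be > 0")
    rng = np.random.default_rng(seed)
    return int(rng.poisson(rate_b)), int(rng.poisson(rate_a))


# ---------------------------------------------------------------------------
# trajectories

def _base_geometry(n: int) -> np.ndarray:
    """Non-degenerate helical Calpha backbone (A)."""
    t = np.arange(n)
    return np.stack([10.0 * np.cos(t * 0.6), 10.0 * np.sin(t * 0.6),
                     1.5 * t], axis=1)


def planted_correlation(cfg: SyntheticConfig) -> np.ndarray:
    """The N x N DCCM the generator plants (1 on the diagonal, rho within
    blocks, 0 elsewhere)."""
    C = np.eye(cfg.n_residues)
    for start, stop, rho in cfg.correlation_blocks:
        for i in range(start, stop):
            for j in range(start, stop):
                if i != j:
                    C[i, j] = rho
    return C


def simulate_trajectory(cfg: SyntheticConfig
                        ) -> tuple[Trajectory, dict, GroundTruth]:
    """Gaussian Calpha trajectory with prescribed RMSF and correlations.

    Per-frame displacements of residue i are isotropic Gaussian with
    total variance a_i^2 (so the expected RMSF is exactly a_i); within
    each configured block, displacements share a common factor giving
    pairwise correlation rho (must be >= 0 or the implied covariance is
    checked for positive semi-definiteness).  Optional global
    rigid-body jitter per frame exercises the superposition step.
    """
    rng = np.random.default_rng(cfg.seed + 2)
    n, f = cfg.n_residues, cfg.n_frames
    amps = (np.full(n, 1.5) if cfg.amplitudes is None
            else np.asarray(cfg.amplitudes, dtype=float))
    if amps.shape != (n,) or np.any(amps < 0):
        raise ValueError("amplitudes must be a non-negative length-N vector")
    for start, stop, _rho in cfg.correlation_blocks:
        if not 0 <= start < stop <= n:
            raise ValueError(
                f"correlation block ({start}, {stop}) outside 0..{n}")
    C = planted_correlation(cfg)
    eigmin = float(np.linalg.eigvalsh(C).min())
    if eigmin < -1e-10:
        raise ValueError("correlation block specification is not PSD")
    # factor structure: z_i = sqrt(rho) g_block + sqrt(1-rho) e_i per axis
    base = _base_geometry(n)
    frames = np.empty((f, n, 3))
    block_of = np.full(n, -1)
    rho_of = np.zeros(n)
    for b, (start, stop, rho) in enumerate(cfg.correlation_blocks):
        block_of[start:stop] = b
        rho_of[start:stop] = rho
    per_axis_sd = amps / math.sqrt(3.0)
    for t in range(f):
        e = rng.normal(size=(n, 3))
        if cfg.correlation_blocks:
            g = rng.normal(size=(len(cfg.correlation_blocks), 3))
            z = np.where(
                (block_of >= 0)[:, None],
                np.sqrt(rho_of)[:, None] * g[block_of.clip(min=0)]
                + np.sqrt(1.0 - rho_of)[:, None] * e,
                e,
            )
        else:
            z = e
        frame = base + per_axis_sd[:, None] * z
        if cfg.rigid_jitter:
            rot = Rotation.random(rng=rng)
            shift = rng.normal(scale=5.0, size=3)
            frame = rot.apply(frame) + shift
        frames[t] = frame
    labels = [("A", i + 1, "ALA") for i in range(n)]
    component_map = cfg.component_map or {"A": list(range(n))}
    traj = Trajectory(residue_labels=labels, frames=frames,
                      frame_interval_ps=1000.0)
    truth = GroundTruth(amplitudes=amps, correlation=C,
                        component_map=component_map)
    return traj, component_map, truth


# ---------------------------------------------------------------------------
# paralog sequences

_NONKR = "ADEFGHILMNQSTVWY"  # C and P excluded to keep digestion plain


def simulate_paralogs(seed: int, length: int = 120,
                      n_discriminant_sites: int = 1
                      ) -> tuple[SequenceRecord, SequenceRecord, GroundTruth]:
    """Two synthetic paralogs differing only by I<->L swaps.

    Paralog B equals paralog A except for ``n_discriminant_sites``
    Ile->Leu substitutions, each placed inside a distinct tryptic
    peptide, emulating isoform-discriminant isobaric peptide pairs.
    Sequences are resampled until the only exact-mass cross-paralog
    matches between distinct peptides are the planted ones, so the
    ground truth is exhaustive.  Truth lists the 1-based peptide
    coordinates hosting each swap.
    """
    if length < 20:
        raise ValueError("length must be >= 20")
    for attempt in range(200):
        rng = np.random.default_rng(seed + 1_000_003 * attempt)
        residues = [str(rng.choice(list(_NONKR))) for _ in range(length)]
        for pos in range(7, length - 1, 8):  # cleavage site every 8 residues
            residues[pos] = "K" if rng.random() < 0.5 else "R"
        seq_a = "".join(residues)
        rec_a = SequenceRecord(id="PARALOG_A_SYN", residues=seq_a,
                               description="synthetic paralog A")
        peptides = [p for p in digest(rec_a, DigestParams())
                    if len(p) >= 4]
        if len(peptides) < n_discriminant_sites:
            continue
        order = rng.permutation(len(peptides))
        chosen = [peptides[i] for i in order[:n_discriminant_sites]]
        a_list = list(seq_a)
        sites = []
        for pep in chosen:
            # plant an Ile inside the peptide (not at the cleavage residue)
            offset = int(rng.integers(0, len(pep) - 1))
            pos = pep.start - 1 + offset
            a_list[pos] = "I"
            sites.append((pep.start, pep.end, pos + 1))
        seq_a = "".join(a_list)
        b_list = list(seq_a)
        for _s, _e, pos1 in sites:
            b_list[pos1 - 1] = "L"
        seq_b = "".join(b_list)
        rec_a = SequenceRecord(id="PARALOG_A_SYN", residues=seq_a,
                               description="synthetic paralog A")
        rec_b = SequenceRecord(id="PARALOG_B_SYN", residues=seq_b,
                               description="synthetic paralog B")
        if _only_planted_matches(rec_a, rec_b, {pos for _s, _e, pos in sites}):
            truth = GroundTruth(discriminant_peptides=[
                {"start": s, "end": e, "site": pos} for s, e, pos in sites])
            return rec_a, rec_b, truth
    raise RuntimeError("could not place the requested discriminant sites")


def _only_planted_matches(rec_a: SequenceRecord, rec_b: SequenceRecord,
                          planted_sites: set[int]) -> bool:
    """True iff the only exact-mass, distinct-sequence cross-paralog
    peptide pairs are those hosting a planted swap."""
    pep_a = {p.sequence: p for p in digest(rec_a, DigestParams())}
    pep_b = {p.sequence: p for p in digest(rec_b, DigestParams())}
    for sa, pa in pep_a.items():
        for sb, pb in pep_b.items():
            if sa == sb:
                continue
            if abs(pa.mass - pb.mass) < 1e-6:
                covers = any(pa.start <= site <= pa.end
                             for site in planted_sites)
                same_span = (pa.start, pa.end) == (pb.start, pb.end)
                if not (covers and same_span):
                    return False
    return True
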