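"""Readers and writers for the external formats the pipeline touches.

Formats: FASTA (protein sequences, via Bio.SeqIO), TSV species and
identification tables (pandas), and single- or multi-model PDB
coordinate files (gemmi).  All residue indices are 1-based.  Tables are
UTF-8 TSV with a mandatory header line and ``.`` for absent optional
fields; writers prepend comment lines with the tool version and a
configuration hash.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

CANONICAL_AA = set("ACDEFGHIKLMNPQRSTVWY")

SPECIES_COLUMNS = [
    "protein_id", "species_type", "residue_i", "residue_j",
    "condition", "replicate", "peak_height",
]

IDENTIFICATION_COLUMNS = [
    "peptide_sequence", "protein_id", "record_class", "protein_score",
    "discriminant_score", "expectation", "slip_score", "xl_score", "fdr",
    "mass_error_ppm", "charge", "miscleavages", "modifications",
    "intensity", "condition",
]


class FormatError(ValueError):
    """Raised when an input file violates the documented dialect."""


@dataclass(frozen=True)
class SequenceRecord:
    """A protein sequence with canonical one-letter residues.

    Non-canonical letters (B, Z, X, U, ...) are rejected on
    construction: downstream peptide masses would be undefined.
    """

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.residues:
            raise FormatError(f"empty sequence for record {self.id!r}")
        bad = set(self.residues) - CANONICAL_AA
        if bad:
            raise FormatError(
                f"non-canonical residue letters {sorted(bad)} in {self.id!r}; "
                "only the 20 canonical amino acids are supported"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class CrosslinkSpeciesRecord:
    """One MS-quantified cross-linked or dead-end (mono-linked) species.

    ``peak_height`` is the XIC apex intensity in arbitrary units;
    intensities are never rescaled on input because every downstream
    statistic is a ratio.  ``residue_j`` is present iff the species is a
    genuine cross-link; a dead-end carries a single modified lysine.
    """

    protein_id: str
    species_type: str  # "crosslink" | "deadend"
    residue_i: int
    condition: str
    replicate: int
    peak_height: float
    residue_j: int | None = None

    def __post_init__(self) -> None:
        if self.species_type not in ("crosslink", "deadend"):
            raise FormatError(f"unknown species_type {self.species_type!r}")
        if self.species_type == "crosslink":
            if self.residue_j is None:
                raise FormatError("crosslink species requires residue_j")
            if not self.residue_i < self.residue_j:
                raise FormatError(
                    f"crosslink requires residue_i < residue_j, got "
                    f"({self.residue_i}, {self.residue_j})"
                )
        elif self.residue_j is not None:
            raise FormatError("deadend species must not carry residue_j")
        if self.residue_i < 1:
            raise FormatError("residue indices are 1-based positive integers")
        if not np.isfinite(self.peak_height) or self.peak_height < 0:
            raise FormatError(f"peak_height must be >= 0, got {self.peak_height}")
        if self.replicate < 1:
            raise FormatError("replicate is a positive integer")

    @property
    def key(self) -> tuple:
        return (self.protein_id, self.species_type, self.residue_i,
                self.residue_j, self.condition, self.replicate)


@dataclass(frozen=True)
class IdentificationRecord:
    """One row of a search-engine identification/intensity export.

    ``record_class`` selects which score fields are meaningful:
    ``protein`` (protein_score, discriminant_score, expectation),
    ``peptide``/``phosphopeptide`` (expectation; phosphopeptides
    additionally slip_score and localized ``modifications``),
    ``crosslink`` (xl_score, fdr, mass_error_ppm).
    """

    peptide_sequence: str
    protein_id: str
    record_class: str
    condition: str = ""
    protein_score: float | None = None
    discriminant_score: float | None = None
    expectation: float | None = None
    slip_score: float | None = None
    xl_score: float | None = None
    fdr: float | None = None
    mass_error_ppm: float | None = None
    charge: int = 1
    miscleavages: int = 0
    modifications: tuple[tuple[int, str], ...] = ()
    intensity: float = 0.0

    _CLASSES = ("protein", "peptide", "phosphopeptide", "crosslink")

    def __post_init__(self) -> None:
        if self.record_class not in self._CLASSES:
            raise FormatError(f"unknown record_class {self.record_class!r}")
        if self.expectation is not None and self.expectation < 0:
            raise FormatError("expectation must be >= 0")
        if self.fdr is not None and not 0.0 <= self.fdr <= 1.0:
            raise FormatError("fdr must lie in [0, 1]")
        if self.intensity < 0:
            raise FormatError("intensity must be >= 0")
        if self.charge < 1:
            raise FormatError("charge is a positive integer")
        if self.miscleavages < 0:
            raise FormatError("miscleavages is a non-negative integer")


@dataclass
class Trajectory:
    """Frames x residues x 3 Calpha coordinates in Angstrom.

    ``residue_labels`` is an ordered list of (chain_id, residue_index,
    residue_name) shared by every frame; trajectories are rectangular by
    construction.
    """

    residue_labels: list[tuple[str, int, str]]
    frames: np.ndarray  # (F, N, 3), float
    frame_interval_ps: float | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise FormatError(f"frames must be (F, N, 3), got {self.frames.shape}")
        if self.frames.shape[0] < 1 or self.frames.shape[1] < 1:
            raise FormatError("trajectory needs >= 1 frame and >= 1 residue")
        if self.frames.shape[1] != len(self.residue_labels):
            raise FormatError("residue_labels length must match frame width")
        if not np.all(np.isfinite(self.frames)):
            raise FormatError("coordinates must be finite")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_residues(self) -> int:
        return self.frames.shape[1]

    def residue_index(self, residue: int, chain: str | None = None) -> int:
        """Positional index of a 1-based residue number (optionally per chain)."""
        for pos, (ch, resnum, _name) in enumerate(self.residue_labels):
            if resnum == residue and (chain is None or ch == chain):
                return pos
        raise KeyError(f"residue {residue} (chain={chain}) not in trajectory")


@dataclass
class RunConfig:
    """Pipeline-wide configuration gathered in one hashable record."""

    seed: int = 0
    max_span_angstrom: float = 30.0
    sd_multiplier: float = 1.5
    min_separation: int = 8
    alpha: float = 0.05
    mr_min: float = 700.0
    mr_max: float = 2800.0
    max_miscleavages: int = 0
    output_dir: str = "."
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.max_span_angstrom <= 0:
            raise ValueError("max_span_angstrom must be positive")
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must lie in (0, 1]")
        if self.mr_min >= self.mr_max:
            raise ValueError("mr_min must be < mr_max")

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file into validated :class:`SequenceRecord` objects.

    Wrapped sequence lines are concatenated; record order is preserved.
    An empty file yields an empty list; a header with no sequence or a
    sequence line before any header is an error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text()
    if text.strip() and not text.lstrip().startswith(">"):
        raise FormatError(f"{path}: sequence data before any FASTA header")
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if not seq:
            raise FormatError(f"{path}: empty sequence for header {rec.id!r}")
        records.append(SequenceRecord(id=rec.id, residues=seq,
                                      description=rec.description))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path,
                width: int = 60) -> None:
    bio = [
        _BioSeqRecord(Seq(r.residues), id=r.id,
                      description=r.description or "")
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


# ---------------------------------------------------------------------------
# TSV tables

def _comment_header(config_hash: str | None) -> str:
    from epiconform import __version__
    h = config_hash if config_hash is not None else "none"
    return f"# epiconform {__version__} config_hash={h}\n"


def read_species_table(path: str | Path) -> list[CrosslinkSpeciesRecord]:
    """Read a cross-link species TSV into validated records.

    Columns: protein_id, species_type, residue_i, residue_j, condition,
    replicate, peak_height.  ``residue_j`` is ``.`` for dead-ends.
    Duplicate (protein, type, residues, condition, replicate) keys are
    rejected.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = [c for c in SPECIES_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing species-table columns {missing}")
    records: list[CrosslinkSpeciesRecord] = []
    seen: set[tuple] = set()
    for row in df.itertuples(index=False):
        rj = None if row.residue_j in (".", "", None) or pd.isna(row.residue_j) \
            else int(row.residue_j)
        rec = CrosslinkSpeciesRecord(
            protein_id=str(row.protein_id),
            species_type=str(row.species_type),
            residue_i=int(row.residue_i),
            residue_j=rj,
            condition=str(row.condition),
            replicate=int(row.replicate),
            peak_height=float(row.peak_height),
        )
        if rec.key in seen:
            raise FormatError(f"{path}: duplicate species key {rec.key}")
        seen.add(rec.key)
        records.append(rec)
    return records


def write_species_table(records: Iterable[CrosslinkSpeciesRecord],
                        path: str | Path,
                        config_hash: str | None = None) -> None:
    rows = []
    for r in records:
        rows.append({
            "protein_id": r.protein_id,
            "species_type": r.species_type,
            "residue_i": r.residue_i,
            "residue_j": "." if r.residue_j is None else r.residue_j,
            "condition": r.condition,
            "replicate": r.replicate,
            "peak_height": repr(float(r.peak_height)),
        })
    df = pd.DataFrame(rows, columns=SPECIES_COLUMNS)
    with open(path, "w") as fh:
        fh.write(_comment_header(config_hash))
        df.to_csv(fh, sep="\t", index=False)


def _fmt_opt(value) -> str:
    return "." if value is None else repr(float(value))


def _parse_opt(value) -> float | None:
    if value in (".", "", None) or (isinstance(value, float) and np.isnan(value)):
        return None
    return float(value)


def read_identification_table(path: str | Path) -> list[IdentificationRecord]:
    """Read an identification/intensity TSV (columns mirror IdentificationRecord)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = [c for c in IDENTIFICATION_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing identification columns {missing}")
    records = []
    for row in df.itertuples(index=False):
        mods: tuple[tuple[int, str], ...] = ()
        if row.modifications not in (".", "", None) and not pd.isna(row.modifications):
            mods = tuple(
                (int(site), kind)
                for site, kind in (m.split(":") for m in str(row.modifications).split(";"))
            )
        records.append(IdentificationRecord(
            peptide_sequence=str(row.peptide_sequence),
            protein_id=str(row.protein_id),
            record_class=str(row.record_class),
            condition="" if pd.isna(row.condition) else str(row.condition),
            protein_score=_parse_opt(row.protein_score),
            discriminant_score=_parse_opt(row.discriminant_score),
            expectation=_parse_opt(row.expectation),
            slip_score=_parse_opt(row.slip_score),
            xl_score=_parse_opt(row.xl_score),
            fdr=_parse_opt(row.fdr),
            mass_error_ppm=_parse_opt(row.mass_error_ppm),
            charge=int(row.charge),
            miscleavages=int(row.miscleavages),
            modifications=mods,
            intensity=float(row.intensity),
        ))
    return records


def write_identification_table(records: Iterable[IdentificationRecord],
                               path: str | Path,
                               config_hash: str | None = None) -> None:
    rows = []
    for r in records:
        mods = ";".join(f"{site}:{kind}" for site, kind in r.modifications) or "."
        rows.append({
            "peptide_sequence": r.peptide_sequence,
            "protein_id": r.protein_id,
            "record_class": r.record_class,
            "protein_score": _fmt_opt(r.protein_score),
            "discriminant_score": _fmt_opt(r.discriminant_score),
            "expectation": _fmt_opt(r.expectation),
            "slip_score": _fmt_opt(r.slip_score),
            "xl_score": _fmt_opt(r.xl_score),
            "fdr": _fmt_opt(r.fdr),
            "mass_error_ppm": _fmt_opt(r.mass_error_ppm),
            "charge": r.charge,
            "miscleavages": r.miscleavages,
            "modifications": mods,
            "intensity": repr(float(r.intensity)),
            "condition": r.condition,
        })
    df = pd.DataFrame(rows, columns=IDENTIFICATION_COLUMNS)
    with open(path, "w") as fh:
        fh.write(_comment_header(config_hash))
        df.to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# PDB coordinates

def read_structure(path: str | Path) -> Trajectory:
    """Read a single- or multi-model PDB file into a Calpha trajectory.

    One frame per MODEL block (a single-model file yields F = 1); only
    Calpha atoms are retained.  Models whose residue sets differ are a
    hard error: trajectories must be rectangular.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    st = gemmi.read_pdb(str(path))
    if len(st) == 0:
        raise FormatError(f"{path}: no models")
    frames = []
    labels_ref: list[tuple[str, int, str]] | None = None
    for model in st:
        labels = []
        coords = []
        for chain in model:
            for residue in chain:
                for atom in residue:
                    if atom.name == "CA":
                        labels.append((chain.name, residue.seqid.num,
                                       residue.name))
                        coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
                        break
        if not coords:
            raise FormatError(f"{path}: a model contains no CA atoms")
        if labels_ref is None:
            labels_ref = labels
        elif labels != labels_ref:
            raise FormatError(
                f"{path}: models have inconsistent residue sets; "
                "trajectories must be rectangular"
            )
        frames.append(coords)
    assert labels_ref is not None
    return Trajectory(residue_labels=labels_ref,
                      frames=np.asarray(frames, dtype=float))


def write_structure(traj: Trajectory, path: str | Path) -> None:
    """Write a Calpha trajectory as a (multi-)model PDB file."""
    st = gemmi.Structure()
    st.name = "epiconform"
    for f in range(traj.n_frames):
        model = gemmi.Model(f + 1)
        chains: dict[str, gemmi.Chain] = {}
        for pos, (chain_id, resnum, resname) in enumerate(traj.residue_labels):
            if chain_id not in chains:
                chains[chain_id] = gemmi.Chain(chain_id)
            residue = gemmi.Residue()
            residue.name = resname
            residue.seqid = gemmi.SeqId(resnum, " ")
            atom = gemmi.Atom()
            atom.name = "CA"
            atom.element = gemmi.Element("C")
            x, y, z = traj.frames[f, pos]
            atom.pos = gemmi.Position(float(x), float(y), float(z))
            residue.add_atom(atom)
            chains[chain_id].add_residue(residue)
        for chain in chains.values():
            model.add_chain(chain)
        st.add_model(model)
    st.setup_entities()
    doc = st.make_pdb_string()
    Path(path).write_text(doc)
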