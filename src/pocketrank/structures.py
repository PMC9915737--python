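"""Reading protein structures and FPocket output.

PDB files are parsed by fixed column position (the format is column-oriented;
whitespace splitting breaks on fused fields).  FPocket descriptor files are
parsed from the ``Pocket N :`` block dialect written by FPocket 3.x/4.x.
Centers of mass are computed over heavy atoms with standard atomic masses by
default; a purely geometric (unweighted) mode is also provided.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gemmi
import numpy as np
from Bio.SeqUtils import seq1

__all__ = [
    "Atom",
    "PocketFeatures",
    "Pocket",
    "ProteinEntry",
    "FEATURE_NAMES",
    "PDBParseError",
    "StructureError",
    "FPocketParseError",
    "parse_pdb",
    "parse_fpocket_info",
    "format_fpocket_info",
    "center_of_mass",
    "read_fpocket_dir",
    "load_entry",
]


class PDBParseError(ValueError):
    """A PDB record could not be parsed; carries the 1-based line number."""


class StructureError(ValueError):
    """The structure is unusable (e.g. no ATOM records at all)."""


class FPocketParseError(ValueError):
    """An FPocket descriptor block is malformed or incomplete."""


#: Canonical order of the 19 FPocket physicochemical descriptors.  This order
#: is the feature order used everywhere downstream (tables, training, models).
FEATURE_NAMES: tuple[str, ...] = (
    "score",
    "druggability_score",
    "n_alpha_spheres",
    "total_sasa",
    "polar_sasa",
    "apolar_sasa",
    "volume",
    "mean_local_hydrophobic_density",
    "mean_alpha_sphere_radius",
    "mean_alpha_sphere_solvent_access",
    "apolar_alpha_sphere_proportion",
    "hydrophobicity_score",
    "volume_score",
    "polarity_score",
    "charge_score",
    "proportion_polar_atoms",
    "alpha_sphere_density",
    "center_mass_max_dist",
    "flexibility",
)

# FPocket info.txt line labels -> canonical descriptor names.  Keys are
# normalized (lowercased, colons and repeated blanks stripped) before lookup,
# so minor dialect drift between FPocket releases is tolerated.
_FPOCKET_LABELS: dict[str, str] = {
    "score": "score",
    "druggability score": "druggability_score",
    "number of alpha spheres": "n_alpha_spheres",
    "total sasa": "total_sasa",
    "polar sasa": "polar_sasa",
    "apolar sasa": "apolar_sasa",
    "volume": "volume",
    "mean local hydrophobic density": "mean_local_hydrophobic_density",
    "mean alpha sphere radius": "mean_alpha_sphere_radius",
    "mean alp. sph. solvent access": "mean_alpha_sphere_solvent_access",
    "apolar alpha sphere proportion": "apolar_alpha_sphere_proportion",
    "hydrophobicity score": "hydrophobicity_score",
    "volume score": "volume_score",
    "polarity score": "polarity_score",
    "charge score": "charge_score",
    "proportion of polar atoms": "proportion_polar_atoms",
    "alpha sphere density": "alpha_sphere_density",
    "cent. of mass - alpha sphere max dist": "center_mass_max_dist",
    "flexibility": "flexibility",
}

# Pretty labels used when re-serializing descriptor blocks (FPocket dialect).
_FPOCKET_PRINT_LABELS: dict[str, str] = {
    canonical: label.capitalize() if canonical != "total_sasa" else "Total SASA"
    for label, canonical in _FPOCKET_LABELS.items()
}
_FPOCKET_PRINT_LABELS.update(
    {
        "total_sasa": "Total SASA",
        "polar_sasa": "Polar SASA",
        "apolar_sasa": "Apolar SASA",
        "mean_alpha_sphere_solvent_access": "Mean alp. sph. solvent access",
        "center_mass_max_dist": "Cent. of mass - Alpha Sphere max dist",
    }
)


@dataclass(frozen=True)
class Atom:
    """One atom from an ATOM/HETATM record."""

    element: str
    coords: tuple[float, float, float]
    record_kind: str  # "ATOM" (standard residue) or "HETATM"
    residue_name: str
    chain_id: str
    residue_number: int
    name: str = ""

    def __post_init__(self) -> None:
        if not all(np.isfinite(self.coords)):
            raise ValueError(f"non-finite coordinates: {self.coords}")


@dataclass(frozen=True)
class PocketFeatures:
    """The 19 FPocket descriptors of one pocket, in canonical order."""

    score: float
    druggability_score: float
    n_alpha_spheres: float
    total_sasa: float
    polar_sasa: float
    apolar_sasa: float
    volume: float
    mean_local_hydrophobic_density: float
    mean_alpha_sphere_radius: float
    mean_alpha_sphere_solvent_access: float
    apolar_alpha_sphere_proportion: float
    hydrophobicity_score: float
    volume_score: float
    polarity_score: float
    charge_score: float
    proportion_polar_atoms: float
    alpha_sphere_density: float
    center_mass_max_dist: float
    flexibility: float

    def __post_init__(self) -> None:
        if self.n_alpha_spheres < 0 or self.n_alpha_spheres != int(self.n_alpha_spheres):
            raise ValueError(
                f"n_alpha_spheres must be a non-negative integer, got {self.n_alpha_spheres}"
            )

    @classmethod
    def from_mapping(cls, values: Mapping[str, float]) -> "PocketFeatures":
        missing = [n for n in FEATURE_NAMES if n not in values]
        if missing:
            raise ValueError(f"missing descriptors: {missing}")
        return cls(**{n: float(values[n]) for n in FEATURE_NAMES})

    def as_vector(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in FEATURE_NAMES], dtype=float)


@dataclass(frozen=True)
class Pocket:
    """One FPocket pocket: 1-based index, descriptors, atoms, 3-D center (A)."""

    pocket_index: int
    features: PocketFeatures
    atoms: tuple[Atom, ...] = ()
    center: tuple[float, float, float] | None = None


@dataclass
class ProteinEntry:
    """One protein-modulator complex moving through the curation pipeline."""

    protein_id: str
    resolution: float | None = None
    sequence: str = ""
    pockets: tuple[Pocket, ...] = ()
    modulator_center: tuple[float, float, float] | None = None
    modulator_count: int = 0
    labels: tuple[int, ...] | None = None
    min_modulator_distance: float | None = None

    def __post_init__(self) -> None:
        if self.labels is not None:
            if len(self.labels) != len(self.pockets):
                raise ValueError("labels length must equal number of pockets")
            if sum(self.labels) > 1:
                raise ValueError("at most one pocket may be labeled positive")

    def with_pockets(self, pockets: Sequence[Pocket]) -> "ProteinEntry":
        return replace(self, pockets=tuple(pockets), labels=None)


# ---------------------------------------------------------------------------
# PDB parsing


def _parse_atom_line(line: str, lineno: int) -> Atom:
    try:
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
    except ValueError as exc:
        raise PDBParseError(f"line {lineno}: malformed coordinate field: {line.rstrip()!r}") from exc
    name = line[12:16].strip()
    element = line[76:78].strip() if len(line) >= 78 else ""
    if not element:
        # Derive from the atom name: first alphabetic character that is not a
        # digit; works for the common C/N/O/S/P heavy atoms of PDB entries.
        for ch in name:
            if ch.isalpha():
                element = ch
                break
    try:
        resnum = int(line[22:26])
    except ValueError as exc:
        raise PDBParseError(f"line {lineno}: malformed residue number: {line.rstrip()!r}") from exc
    return Atom(
        element=element.capitalize(),
        coords=(x, y, z),
        record_kind=line[:6].strip(),
        residue_name=line[17:20].strip(),
        chain_id=line[21],
        residue_number=resnum,
        name=name,
    )


_RESOLUTION_RE = re.compile(r"RESOLUTION\.\s+([0-9]+\.?[0-9]*)\s+ANGSTROM", re.IGNORECASE)


def parse_pdb(text: str, modulator_residue_names: Iterable[str] = ()) -> ProteinEntry:
    """Parse a PDB-format string into a :class:`ProteinEntry` (no pockets yet).

    Parameters
    ----------
    text:
        Full PDB file content.
    modulator_residue_names:
        Three-letter HETATM residue names that count as the allosteric
        modulator.  Each distinct residue instance (chain + residue number)
        counts once toward ``modulator_count``.

    Returns an entry with the resolution (from ``REMARK   2`` when present),
    the one-letter sequence of the longest chain built from ATOM records
    (nonstandard residues become ``X``), and the modulator center of mass when
    exactly one modulator instance is present.
    """
    mod_names = {n.strip().upper() for n in modulator_residue_names}
    resolution: float | None = None
    protein_atoms: list[Atom] = []
    # chain -> ordered residue keys -> 3-letter name
    chains: dict[str, dict[tuple[int, str], str]] = {}
    # modulator residue instance -> atoms
    modulators: dict[tuple[str, int, str, str], list[Atom]] = {}

    for lineno, line in enumerate(text.splitlines(), start=1):
        rec = line[:6]
        if rec.startswith("REMARK") and line[7:10].strip() == "2" and resolution is None:
            m = _RESOLUTION_RE.search(line)
            if m:
                resolution = float(m.group(1))
        elif rec in ("ATOM  ", "HETATM"):
            altloc = line[16] if len(line) > 16 else " "
            if altloc not in (" ", "A"):
                continue
            atom = _parse_atom_line(line, lineno)
            if atom.record_kind == "ATOM":
                protein_atoms.append(atom)
                icode = line[26] if len(line) > 26 else " "
                chains.setdefault(atom.chain_id, {}).setdefault(
                    (atom.residue_number, icode), atom.residue_name
                )
            elif atom.residue_name.upper() in mod_names:
                icode = line[26] if len(line) > 26 else " "
                key = (atom.chain_id, atom.residue_number, icode, atom.residue_name)
                modulators.setdefault(key, []).append(atom)

    if not protein_atoms:
        raise StructureError("no ATOM records found")

    longest = max(chains.values(), key=len)
    sequence = "".join(
        seq1(res3, custom_map={}) if len(res3) == 3 else "X" for res3 in longest.values()
    )
    sequence = sequence.replace(" ", "X")

    mod_count = len(modulators)
    mod_center = None
    if mod_count == 1:
        (atoms,) = modulators.values()
        mod_center = tuple(center_of_mass(atoms))

    return ProteinEntry(
        protein_id="",
        resolution=resolution,
        sequence=sequence,
        modulator_center=mod_center,
        modulator_count=mod_count,
    )


# ---------------------------------------------------------------------------
# FPocket descriptor files

_POCKET_HEADER_RE = re.compile(r"^Pocket\s+(\d+)\s*:?\s*$")


def _normalize_label(label: str) -> str:
    return re.sub(r"\s+", " ", label.strip().rstrip(":").strip()).lower()


def parse_fpocket_info(text: str) -> list[tuple[int, PocketFeatures]]:
    """Parse an FPocket ``*_info.txt`` string into per-pocket descriptors.

    Returns ``(pocket_index, PocketFeatures)`` pairs in file order.  A block
    missing any of the 19 descriptors raises :class:`FPocketParseError` naming
    the pocket and the field; unknown extra lines are ignored.
    """
    records: list[tuple[int, PocketFeatures]] = []
    current_idx: int | None = None
    current: dict[str, float] = {}

    def flush() -> None:
        nonlocal current_idx, current
        if current_idx is None:
            return
        missing = [n for n in FEATURE_NAMES if n not in current]
        if missing:
            raise FPocketParseError(
                f"pocket {current_idx}: missing descriptor(s) {', '.join(missing)}"
            )
        records.append((current_idx, PocketFeatures.from_mapping(current)))
        current_idx, current = None, {}

    for raw in text.splitlines():
        line = raw.strip()
        if not line:
            continue
        header = _POCKET_HEADER_RE.match(line)
        if header:
            flush()
            current_idx = int(header.group(1))
            continue
        if current_idx is None or ":" not in line:
            continue
        label, _, value = line.partition(":")
        canonical = _FPOCKET_LABELS.get(_normalize_label(label))
        if canonical is None:
            continue
        try:
            current[canonical] = float(value.strip())
        except ValueError as exc:
            raise FPocketParseError(
                f"pocket {current_idx}: bad value for {canonical}: {value.strip()!r}"
            ) from exc
    flush()
    return records


def format_fpocket_info(records: Sequence[tuple[int, PocketFeatures]]) -> str:
    """Serialize descriptors back to the FPocket ``info.txt`` dialect."""
    blocks = []
    for idx, feats in records:
        lines = [f"Pocket {idx} :"]
        for name in FEATURE_NAMES:
            value = getattr(feats, name)
            shown = f"{int(value)}" if name == "n_alpha_spheres" else repr(float(value))
            lines.append(f"\t{_FPOCKET_PRINT_LABELS[name]} : \t{shown}")
        blocks.append("\n".join(lines))
    return "\n\n".join(blocks) + ("\n" if blocks else "")


# ---------------------------------------------------------------------------
# Centers of mass


def center_of_mass(atoms: Sequence[Atom], weighting: str = "mass") -> np.ndarray:
    """Center of mass of a set of atoms, in Angstroms.

    ``weighting="mass"`` uses standard atomic masses (hydrogens, usually
    absent from X-ray structures, carry their true small weight when present);
    ``weighting="geometric"`` is the unweighted coordinate mean.
    """
    if len(atoms) == 0:
        raise ValueError("center_of_mass of an empty atom list")
    coords = np.array([a.coords for a in atoms], dtype=float)
    if weighting == "geometric":
        return coords.mean(axis=0)
    if weighting != "mass":
        raise ValueError(f"unknown weighting {weighting!r}")
    masses = np.empty(len(atoms))
    for i, a in enumerate(atoms):
        el = gemmi.Element(a.element)
        if el.name == "X" or el.weight <= 0:
            raise ValueError(
                f"unrecognized element {a.element!r}; use weighting='geometric'"
            )
        masses[i] = el.weight
    return (coords * masses[:, None]).sum(axis=0) / masses.sum()


# ---------------------------------------------------------------------------
# FPocket output directories


def read_fpocket_dir(path: str | Path, weighting: str = "mass") -> list[Pocket]:
    """Read an FPocket output directory (``<name>_out`` layout) into pockets.

    Descriptors come from ``<name>_info.txt``; pocket atoms and hence pocket
    centers come from ``pockets/pocketN_atm.pdb``.
    """
    path = Path(path)
    info_files = sorted(path.glob("*_info.txt"))
    if not info_files:
        raise FileNotFoundError(f"no *_info.txt in {path}")
    records = parse_fpocket_info(info_files[0].read_text())
    pockets = []
    for idx, feats in records:
        atm = path / "pockets" / f"pocket{idx}_atm.pdb"
        atoms: tuple[Atom, ...] = ()
        center = None
        if atm.exists():
            atoms = tuple(
                _parse_atom_line(line, i)
                for i, line in enumerate(atm.read_text().splitlines(), start=1)
                if line[:6] in ("ATOM  ", "HETATM")
            )
            if atoms:
                center = tuple(center_of_mass(atoms, weighting=weighting))
        pockets.append(Pocket(pocket_index=idx, features=feats, atoms=atoms, center=center))
    return pockets


def load_entry(
    pdb_path: str | Path,
    fpocket_dir: str | Path,
    modulator_residue_names: Iterable[str],
    protein_id: str | None = None,
) -> ProteinEntry:
    """Assemble a full entry from a PDB file plus its FPocket output."""
    pdb_path = Path(pdb_path)
    entry = parse_pdb(pdb_path.read_text(), modulator_residue_names)
    entry.protein_id = protein_id or pdb_path.stem
    return entry.with_pockets(read_fpocket_dir(fpocket_dir))
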