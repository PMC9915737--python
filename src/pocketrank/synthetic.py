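"""Synthetic pocket data: grouped feature tables and minimal structure fixtures.

The generator emulates the statistical shape of a curated pocket dataset —
per-protein groups of ~21 pockets, 19 descriptors, exactly one positive per
group — not protein physics.  The positive pocket's descriptors are shifted
along the directions reported for real allosteric sites: higher FPocket
score, volume score and charge score, lower flexibility and total SASA.
Structure fixtures are geometrically exact toy complexes (pocket atom
clusters at known centers, one modulator residue at a chosen distance) that
round-trip through parsing and curation to a known label vector.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from Bio.Data.IUPACData import protein_letters_1to3

from .ltr import RankingDataset
from .structures import FEATURE_NAMES, PocketFeatures, format_fpocket_info

_STANDARD_RESIDUES = tuple(
    three.upper() for three in protein_letters_1to3.values()
)

__all__ = [
    "SyntheticSpec",
    "DEFAULT_EFFECT_SIZES",
    "generate_table",
    "generate_feature_table",
    "StructureFixture",
    "generate_structure_fixture",
]

#: Mean shift (in noise-SD units) applied to the positive pocket's features.
DEFAULT_EFFECT_SIZES: dict[str, float] = {
    "score": 1.5,
    "volume_score": 1.5,
    "charge_score": 1.5,
    "flexibility": -1.0,
    "total_sasa": -1.0,
}


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for the synthetic generator.

    ``pockets_mean`` anchors a shifted-Poisson count model, ``2 + Poisson(mean
    - 2)``, which respects the >= 2 pockets-per-protein minimum (its
    dispersion is therefore tied to the mean).  ``effect_sizes`` are
    per-feature mean shifts, in units of ``noise_sd``, applied to the one
    positive pocket per protein; unlisted features get no shift.
    """

    n_proteins: int = 100
    pockets_mean: float = 21.0
    effect_sizes: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_EFFECT_SIZES)
    )
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins < 1:
            raise ValueError("n_proteins must be >= 1")
        if self.pockets_mean < 2:
            raise ValueError("pockets_mean must be >= 2")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        unknown = set(self.effect_sizes) - set(FEATURE_NAMES)
        if unknown:
            raise ValueError(f"unknown features in effect_sizes: {sorted(unknown)}")
        if not all(np.isfinite(list(self.effect_sizes.values()))):
            raise ValueError("effect sizes must be finite")


def _shift_vector(spec: SyntheticSpec) -> np.ndarray:
    shift = np.zeros(len(FEATURE_NAMES))
    for name, effect in spec.effect_sizes.items():
        shift[FEATURE_NAMES.index(name)] = effect * spec.noise_sd
    return shift


def generate_table(spec: SyntheticSpec) -> pd.DataFrame:
    """Synthetic feature table in the curation-module layout.

    Per protein: pocket count ~ 2 + Poisson(mean - 2); features are iid
    normals with SD ``noise_sd`` around zero; one uniformly chosen pocket is
    positive and receives the effect shifts.  Fully reproducible from the
    seed.
    """
    rng = np.random.default_rng(spec.seed)
    shift = _shift_vector(spec)
    frames = []
    for i in range(spec.n_proteins):
        n = 2 + rng.poisson(spec.pockets_mean - 2)
        X = rng.normal(0.0, spec.noise_sd, size=(n, len(FEATURE_NAMES)))
        pos = int(rng.integers(n))
        X[pos] += shift
        frame = pd.DataFrame(X, columns=list(FEATURE_NAMES))
        frame.insert(0, "pocket_index", np.arange(1, n + 1))
        frame.insert(0, "protein_id", f"synth_{i:04d}")
        frame["label"] = (np.arange(n) == pos).astype(int)
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)


def generate_feature_table(spec: SyntheticSpec) -> RankingDataset:
    """Grouped ranking dataset drawn from ``spec`` (see :func:`generate_table`)."""
    return RankingDataset.from_table(generate_table(spec))


# ---------------------------------------------------------------------------
# Structure fixtures


def _pdb_line(
    record: str,
    serial: int,
    name: str,
    resname: str,
    chain: str,
    resseq: int,
    xyz: tuple[float, float, float],
    element: str,
) -> str:
    return (
        f"{record:<6s}{serial:>5d} {name:<4s} {resname:>3s} {chain}{resseq:>4d}    "
        f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.00:6.2f}{0.00:6.2f}"
        f"          {element:>2s}"
    )


@dataclass
class StructureFixture:
    """A synthetic protein-modulator complex plus its FPocket-dialect output."""

    protein_id: str
    pdb_text: str
    info_text: str
    pocket_pdbs: tuple[str, ...]
    manifest_row: tuple[str, str]  # (protein_id, modulator residue name)
    pocket_centers: np.ndarray
    modulator_position: np.ndarray | None
    target_pocket: int

    def write(self, directory: str | Path) -> tuple[Path, Path]:
        """Write ``<id>.pdb`` and the ``<id>_out`` FPocket layout; return both."""
        directory = Path(directory)
        pdb_path = directory / f"{self.protein_id}.pdb"
        out_dir = directory / f"{self.protein_id}_out"
        (out_dir / "pockets").mkdir(parents=True, exist_ok=True)
        pdb_path.write_text(self.pdb_text)
        (out_dir / f"{self.protein_id}_info.txt").write_text(self.info_text)
        for i, text in enumerate(self.pocket_pdbs, start=1):
            (out_dir / "pockets" / f"pocket{i}_atm.pdb").write_text(text)
        return pdb_path, out_dir


def _fixture_features(rng: np.random.Generator, n_pockets: int) -> list[PocketFeatures]:
    X = rng.normal(0.0, 1.0, size=(n_pockets, len(FEATURE_NAMES)))
    feats = []
    for row in X:
        values = dict(zip(FEATURE_NAMES, row))
        values["n_alpha_spheres"] = float(int(abs(values["n_alpha_spheres"]) * 20) + 5)
        feats.append(PocketFeatures.from_mapping(values))
    return feats


def generate_structure_fixture(
    spec: SyntheticSpec,
    n_pockets: int = 3,
    modulator_distance: float = 4.0,
    target_pocket: int = 2,
    n_modulators: int = 1,
    resolution: float | None = 2.1,
    protein_id: str = "SYN1",
    modulator_name: str = "MOD",
    residues: tuple[str, ...] | None = None,
) -> StructureFixture:
    """Build a toy complex with exactly known geometry.

    Pocket ``k`` is a symmetric 4-carbon cluster centered at ``(40(k-1), 0,
    0)`` (so its center of mass is exact); the modulator is a single carbon
    placed ``modulator_distance`` Angstroms from the target pocket's center
    along +y.  With ``n_modulators > 1`` extra modulator residue instances are
    emitted (the curation pipeline must then drop the entry); with a distance
    beyond the labeling threshold the entry is dropped for reason "distance".

    ``residues`` fixes the 3-letter residue names of the chain (cycled over
    the 4 atoms per pocket) so fixture sequences — and hence pairwise
    identities in curation tests — are fully controlled; by default they are
    drawn from the 20 standard amino acids using ``spec.seed``.
    """
    if not (1 <= target_pocket <= n_pockets):
        raise ValueError("target_pocket out of range")
    rng = np.random.default_rng(spec.seed)
    n_residues = 4 * n_pockets
    if residues is None:
        chain_residues = [
            _STANDARD_RESIDUES[i] for i in rng.integers(len(_STANDARD_RESIDUES), size=n_residues)
        ]
    else:
        chain_residues = [residues[i % len(residues)] for i in range(n_residues)]
    centers = np.array([[40.0 * k, 0.0, 0.0] for k in range(n_pockets)])
    offsets = np.array(
        [[1.2, 0.0, 0.0], [-1.2, 0.0, 0.0], [0.0, 1.2, 0.0], [0.0, -1.2, 0.0]]
    )

    lines: list[str] = []
    if resolution is not None:
        lines.append(f"REMARK   2 RESOLUTION.    {resolution:.2f} ANGSTROMS.")
    pocket_pdbs: list[str] = []
    serial = 1
    resseq = 1
    for k in range(n_pockets):
        cluster: list[str] = []
        for off in offsets:
            line = _pdb_line(
                "ATOM", serial, "CA", chain_residues[resseq - 1], "A", resseq,
                tuple(centers[k] + off), "C",
            )
            lines.append(line)
            cluster.append(line)
            serial += 1
            resseq += 1
        pocket_pdbs.append("\n".join(cluster) + "\n")

    mod_pos = centers[target_pocket - 1] + np.array([0.0, modulator_distance, 0.0])
    positions = [mod_pos]
    for extra in range(1, n_modulators):
        positions.append(mod_pos + np.array([0.0, 0.0, 25.0 * extra]))
    for m, pos in enumerate(positions):
        lines.append(
            _pdb_line("HETATM", serial, "C1", modulator_name, "A", 900 + m, tuple(pos), "C")
        )
        serial += 1
    lines.append("END")

    info_text = format_fpocket_info(
        list(enumerate(_fixture_features(rng, n_pockets), start=1))
    )
    return StructureFixture(
        protein_id=protein_id,
        pdb_text="\n".join(lines) + "\n",
        info_text=info_text,
        pocket_pdbs=tuple(pocket_pdbs),
        manifest_row=(protein_id, modulator_name),
        pocket_centers=centers,
        modulator_position=mod_pos if n_modulators == 1 else None,
        target_pocket=target_pocket,
    )
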