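"""Template registry and floor-residue mapping.

The "three floors" model places nine residues (3 floors x 3 sites, on
helices D, E and F, one helix pitch ~5.4 A apart) lining the product
elongation tunnel of a trans-prenyltransferase.  Each registry template
carries its sequence and the 1-based positions of those nine sites; after a
query is globally aligned to its best template, the template's annotated
positions are projected through the alignment columns onto the query.

The shipped default registry is a synthetic stand-in: templates are keyed by
the PDB IDs of the eleven curated reference enzymes, but their sequences and
floor annotations are deterministically generated fixtures (see
``transpt.synthetic.build_synthetic_registry``), not PDB-derived chains.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterator

from .alignment import GAP, TemplateMatch
from .formats_io import AMINO_ACIDS, FormatError, ProductClass, ProteinSequence

__all__ = [
    "Template",
    "TemplateRegistry",
    "FloorAssignment",
    "FloorSite",
    "RegistryError",
    "TEMPLATE_ORDER",
    "KINGDOMS",
    "load_registry",
    "save_registry",
    "default_registry",
    "map_floor_residues",
]

#: Fixed registry order of the eleven reference templates.
TEMPLATE_ORDER = (
    "2FOR", "3OYR", "3QQV", "3PKO", "1WMW", "3Q2Q",
    "5E8H", "2E8W", "1FPS", "3AQ0", "1WY0",
)

KINGDOMS = ("Archaea", "Bacteria", "Eukarya")


class RegistryError(ValueError):
    """Raised for malformed template registries."""


@dataclass(frozen=True)
class Template:
    """A reference enzyme with annotated floor-site positions.

    ``floor_positions[f][s]`` is the 1-based sequence position of floor
    ``f+1`` site ``s+1`` (floors top to bottom).
    """

    pdb_id: str
    sequence: ProteinSequence
    floor_positions: tuple[tuple[int, int, int], ...]
    product_class: ProductClass
    kingdom: str

    def __post_init__(self) -> None:
        if len(self.pdb_id) != 4:
            raise RegistryError(f"template id {self.pdb_id!r} is not a 4-character PDB id")
        if self.kingdom not in KINGDOMS:
            raise RegistryError(f"{self.pdb_id}: unknown kingdom {self.kingdom!r}")
        flat = [p for floor in self.floor_positions for p in floor]
        if len(self.floor_positions) != 3 or any(len(f) != 3 for f in self.floor_positions):
            raise RegistryError(f"{self.pdb_id}: expected 3 floors x 3 sites")
        if len(set(flat)) != 9:
            raise RegistryError(f"{self.pdb_id}: floor positions must be 9 distinct values")
        for p in flat:
            if not 1 <= p <= len(self.sequence):
                raise RegistryError(
                    f"{self.pdb_id}: floor position {p} outside sequence "
                    f"(length {len(self.sequence)})"
                )

    def floor_residues(self) -> tuple[tuple[str, str, str], ...]:
        """The template's own residues at the nine floor sites."""
        seq = self.sequence.residues
        return tuple(
            tuple(seq[p - 1] for p in floor) for floor in self.floor_positions
        )


class TemplateRegistry:
    """Ordered collection of templates keyed by PDB id."""

    def __init__(self, templates: list[Template], version: str = "unversioned") -> None:
        ids = [t.pdb_id for t in templates]
        dup = {i for i in ids if ids.count(i) > 1}
        if dup:
            raise RegistryError(f"duplicate template id(s): {sorted(dup)}")
        self._templates = list(templates)
        self._by_id = {t.pdb_id: t for t in templates}
        self.version = version

    def __iter__(self) -> Iterator[Template]:
        return iter(self._templates)

    def __len__(self) -> int:
        return len(self._templates)

    def __contains__(self, pdb_id: str) -> bool:
        return pdb_id in self._by_id

    def __getitem__(self, pdb_id: str) -> Template:
        try:
            return self._by_id[pdb_id]
        except KeyError:
            raise RegistryError(f"template {pdb_id!r} not in registry") from None

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(t.pdb_id for t in self._templates)


@dataclass(frozen=True)
class FloorSite:
    """One floor-site entry of a query: a residue with its 1-based query
    position, or a gap (no residue aligned to the template site)."""

    residue: str | None  # one-letter code, None for a gap
    position: int | None  # 1-based query position, None for a gap

    @property
    def is_gap(self) -> bool:
        return self.residue is None

    @property
    def cell(self) -> str:
        """Report-cell rendering, e.g. 'L121' or '-'."""
        return GAP if self.is_gap else f"{self.residue}{self.position}"


@dataclass(frozen=True)
class FloorAssignment:
    """The query residues occupying the nine floor sites.

    ``sites[f][s]`` (0-based indices) is the :class:`FloorSite` for floor
    ``f+1``, site ``s+1``.
    """

    sites: tuple[tuple[FloorSite, FloorSite, FloorSite], ...]
    template_id: str = "manual"
    identity: float = 1.0

    def __post_init__(self) -> None:
        if len(self.sites) != 3 or any(len(f) != 3 for f in self.sites):
            raise RegistryError("floor assignment requires 3 floors x 3 sites")

    @property
    def has_gap(self) -> bool:
        return any(site.is_gap for floor in self.sites for site in floor)

    def residues(self) -> tuple[tuple[str | None, ...], ...]:
        return tuple(tuple(s.residue for s in floor) for floor in self.sites)

    @classmethod
    def from_residues(
        cls,
        floor1: tuple[str, str, str],
        floor2: tuple[str, str, str],
        floor3: tuple[str, str, str],
    ) -> "FloorAssignment":
        """Build an assignment directly from residue codes (positions
        unknown); used for desk calculations on published floor residues."""
        floors = []
        pos = 1
        for floor in (floor1, floor2, floor3):
            row = []
            for aa in floor:
                aa = _three_to_one(aa)
                row.append(FloorSite(residue=aa, position=pos))
                pos += 1
            floors.append(tuple(row))
        return cls(sites=tuple(floors))


_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


def _three_to_one(aa: str) -> str:
    aa = aa.strip().upper()
    if len(aa) == 1:
        if aa not in AMINO_ACIDS:
            raise FormatError(f"unknown residue code {aa!r}")
        return aa
    try:
        return _THREE_TO_ONE[aa]
    except KeyError:
        raise FormatError(f"unknown residue code {aa!r}") from None


# ---------------------------------------------------------------------------
# Registry file format: TSV, one template per row, bit-exact round-trip.
# Columns: pdb_id, kingdom, product_class, floor_positions (nine
# comma-separated 1-based integers, floor-major), sequence.
# ---------------------------------------------------------------------------

_REGISTRY_HEADER = "pdb_id\tkingdom\tproduct_class\tfloor_positions\tsequence"


def save_registry(registry: TemplateRegistry, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# transpt template registry\tversion={registry.version}\n")
        fh.write(_REGISTRY_HEADER + "\n")
        for tpl in registry:
            flat = ",".join(
                str(p) for floor in tpl.floor_positions for p in floor
            )
            fh.write(
                f"{tpl.pdb_id}\t{tpl.kingdom}\t{tpl.product_class}\t{flat}\t"
                f"{tpl.sequence.residues}\n"
            )


def load_registry(path: str | Path) -> TemplateRegistry:
    """Load a registry file, validating every template invariant."""
    path = Path(path)
    version = "unversioned"
    templates: list[Template] = []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise RegistryError(f"{path}: empty registry file")
    if lines[0].startswith("#"):
        for token in lines[0].split("\t"):
            if token.startswith("version="):
                version = token[len("version="):]
        lines = lines[1:]
    if not lines or lines[0] != _REGISTRY_HEADER:
        raise RegistryError(f"{path}: missing registry header line")
    for ln in lines[1:]:
        fields = ln.split("\t")
        if len(fields) != 5:
            raise RegistryError(f"{path}: malformed registry row: {ln[:60]!r}")
        pdb_id, kingdom, pclass, flat, seq = fields
        positions = [int(x) for x in flat.split(",")]
        if len(positions) != 9:
            raise RegistryError(f"{path}: template {pdb_id}: expected 9 floor positions")
        floors = tuple(
            tuple(positions[i : i + 3]) for i in range(0, 9, 3)
        )
        templates.append(
            Template(
                pdb_id=pdb_id,
                sequence=ProteinSequence(id=pdb_id, residues=seq),
                floor_positions=floors,  # type: ignore[arg-type]
                product_class=ProductClass.parse(pclass),
                kingdom=kingdom,
            )
        )
    return TemplateRegistry(templates, version=version)


def default_registry() -> TemplateRegistry:
    """The shipped default registry (synthetic stand-in fixture, 11
    templates in the fixed order)."""
    with resources.as_file(
        resources.files("transpt").joinpath("data/templates_synthetic.tsv")
    ) as p:
        return load_registry(p)


# ---------------------------------------------------------------------------
# Floor projection
# ---------------------------------------------------------------------------

def map_floor_residues(match: TemplateMatch, template: Template) -> FloorAssignment:
    """Project the template's annotated floor positions through the
    alignment onto the query.

    For each annotated template position, returns the query residue in the
    same alignment column, or a gap marker if the query row has a gap there.
    An 'X' at a floor site is unscorable and raises :class:`RegistryError`.
    """
    if match.template_id != template.pdb_id:
        raise RegistryError(
            f"alignment is against {match.template_id}, not {template.pdb_id}"
        )
    aln = match.alignment
    # 1-based query position per alignment column (position of the residue
    # at that column if non-gap)
    qpos = 0
    col_qpos: list[int | None] = []
    for ch in aln.query_row:
        if ch != GAP:
            qpos += 1
            col_qpos.append(qpos)
        else:
            col_qpos.append(None)

    floors = []
    for f, floor in enumerate(template.floor_positions, start=1):
        row = []
        for s, tpos in enumerate(floor, start=1):
            col = aln.subject_columns[tpos - 1]
            q_res = aln.query_row[col]
            if q_res == GAP:
                row.append(FloorSite(residue=None, position=None))
            elif q_res == "X":
                raise RegistryError(
                    f"query has unscorable residue 'X' at floor {f} site {s} "
                    f"(query position {col_qpos[col]})"
                )
            else:
                row.append(FloorSite(residue=q_res, position=col_qpos[col]))
        floors.append(tuple(row))
    return FloorAssignment(
        sites=tuple(floors), template_id=template.pdb_id, identity=match.identity
    )
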