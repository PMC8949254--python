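"""Protein module catalog and assembly of multifunctional repeat proteins.

The designed carriers are built from short functional units: a 13-residue
calmodulin-derived metal-binding site (MBS) that chelates Gd3+, elastin-like
polypeptide (ELP) VPGXG pentapeptide repeats forming a mildly hydrophobic
scaffold, the cationic nucleolin-binding F3 peptide, an integrin-binding RGD
unit, and flexible Gly/Ser linkers.  An :class:`AssemblyRecipe` lists modules
with copy counts; :func:`assemble` concatenates them, optionally inserting the
Gly-Ser dipeptide that a BglII/BamHI hybrid restriction site encodes between
tandem-multimerized copies, and records per-residue provenance spans.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping

__all__ = [
    "Role",
    "JunctionPolicy",
    "ProteinModule",
    "AssemblyRecipe",
    "DesignedConstruct",
    "ModuleResolutionError",
    "build_catalog",
    "assemble",
    "count_motifs",
    "effective_ligand_concentration",
    "DEFAULT_MOTIF_DEFS",
    "W4_RECIPE",
    "construct_recipes",
]

CANONICAL_AA = set("ACDEFGHIKLMNPQRSTVWY")


class Role(str, Enum):
    METAL_SITE = "metal_site"
    STRUCTURAL = "structural"
    LIGAND = "ligand"
    LINKER = "linker"
    REPORTER = "reporter"
    TAG = "tag"


class JunctionPolicy(str, Enum):
    SEAMLESS = "seamless"
    GS_AT_TANDEM_JUNCTIONS = "gly_ser_at_tandem_junctions"


class ModuleResolutionError(KeyError):
    """A recipe references a module name absent from the catalog."""


@dataclass(frozen=True)
class ProteinModule:
    """One functional building block (amino-acid unit)."""

    name: str
    aa_sequence: str
    role: Role
    source: str = ""

    def __post_init__(self) -> None:
        if not self.aa_sequence:
            raise ValueError(f"module {self.name!r}: empty sequence")
        bad = set(self.aa_sequence) - CANONICAL_AA
        if bad:
            raise ValueError(
                f"module {self.name!r}: non-canonical residues {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.aa_sequence)


@dataclass(frozen=True)
class AssemblyRecipe:
    """Ordered multimerization plan: (module_name, copy_count) items."""

    name: str
    items: tuple[tuple[str, int], ...]
    junction_policy: JunctionPolicy = JunctionPolicy.SEAMLESS

    def __post_init__(self) -> None:
        object.__setattr__(self, "items", tuple((str(n), int(c)) for n, c in self.items))
        for mod_name, count in self.items:
            if count < 1:
                raise ValueError(f"{self.name}: copy_count for {mod_name!r} must be >= 1")

    def validate(self, catalog: Mapping[str, ProteinModule]) -> None:
        for mod_name, _ in self.items:
            if mod_name not in catalog:
                raise ModuleResolutionError(mod_name)


@dataclass
class DesignedConstruct:
    """Assembled protein with per-residue provenance.

    ``spans`` are 0-based half-open (start, end, module_name) triples tiling
    the sequence; Gly-Ser dipeptides introduced by restriction-site junctions
    are labelled ``"junction"``.
    """

    name: str
    aa_sequence: str
    spans: list[tuple[int, int, str]] = field(default_factory=list)
    motif_counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        pos = 0
        for start, end, _ in self.spans:
            if start != pos or end < start:
                raise ValueError("spans must tile the sequence without gaps")
            pos = end
        if self.spans and pos != len(self.aa_sequence):
            raise ValueError("spans do not cover the full sequence")

    def module_span_count(self, module_name: str) -> int:
        return sum(1 for _, _, n in self.spans if n == module_name)


# ---------------------------------------------------------------------------
# Catalog
# ---------------------------------------------------------------------------

MBS_SEQ = "DKDGDGTITTKEL"  # human calmodulin D21-L33 Ca2+ loop
F3_SEQ = "KDEPQRRSARLSAKPAPPKPEPKPKKAPAKK"  # HMGN2 fragment, nucleolin ligand
ELP_S = "VPGSG"
ELP_Y = "VPGYG"
RGD_CORE = "AVTGRGD"

# Synthetic placeholder standing in for the commercial EmGFP reporter, whose
# exact sequence the module catalog treats as a replaceable configuration
# entry.  GFP-like length/composition only; not a real GFP sequence.
EMGFP_PLACEHOLDER_SYNTHETIC = (
    "MSKGEELFTGVVPILVELDGDVNGHKFSVSGEGEGDATYGKLTLKFICTTGKLPVPWPTL"
    "VTTLTYGVQCFSRYPDHMKQHDFFKSAMPEGYVQERTIFFKDDGNYKTRAEVKFEGDTLV"
    "NRIELKGIDFKEDGNILGHKLEYNYNSHNVYIMADKQKNGIKVNFKIRHNIEDGSVQLAD"
    "HYQQNTPIGDGPVLLPDNHYLSTQSALSKDPNEKRDHMVLLEFVTAAGITLGMDELYK"
)


def build_catalog(emgfp_sequence: str | None = None) -> dict[str, ProteinModule]:
    """Return the module catalog used to build the Gd3+-carrier proteins.

    Parameters
    ----------
    emgfp_sequence
        Replacement sequence for the EmGFP reporter entry; by default a
        synthetic GFP-like placeholder is used.
    """
    modules = [
        ProteinModule("M", MBS_SEQ, Role.METAL_SITE, "calmodulin (human) D21-L33"),
        ProteinModule("E(Y)", ELP_Y + ELP_S, Role.STRUCTURAL, "ELP, Tyr + Ser guest"),
        ProteinModule("E", ELP_S * 4, Role.STRUCTURAL, "ELP, Ser guest x4"),
        ProteinModule("Eend", ELP_S * 2, Role.STRUCTURAL, "ELP, Ser guest x2"),
        ProteinModule("F3", F3_SEQ, Role.LIGAND, "HMGN2 (human), nucleolin ligand"),
        ProteinModule("L", "GGGGS" * 2 + "GGGS", Role.LINKER, "(G4S)2(G3S) scFv linker"),
        ProteinModule(
            "RGD", RGD_CORE + "SG" * 5 + "GS", Role.LIGAND,
            "fibronectin-derived AVTGRGD with (SG)5GS linker tail",
        ),
        ProteinModule(
            "EmGFP",
            emgfp_sequence or EMGFP_PLACEHOLDER_SYNTHETIC,
            Role.REPORTER,
            "synthetic placeholder for the EmGFP reporter (replaceable)",
        ),
        ProteinModule("7His", "HHHHHHH", Role.TAG, "purification tag"),
        ProteinModule("InitTag", "TTPQH", Role.TAG,
                      "translation-enhancing A/C-codon peptide next to the His tag"),
    ]
    return {m.name: m for m in modules}


# The four-site metal-binding core: 2 x (E(Y)-M-E-M) + Eend
MBS4_CORE_ITEMS: tuple[tuple[str, int], ...] = (
    ("E(Y)", 1), ("M", 1), ("E", 1), ("M", 1),
    ("E(Y)", 1), ("M", 1), ("E", 1), ("M", 1),
    ("Eend", 1),
)

# W4 block: F3 + linker + 4MBS core
W4_RECIPE = AssemblyRecipe(
    "W4", (("F3", 1), ("L", 1)) + MBS4_CORE_ITEMS, JunctionPolicy.SEAMLESS
)


def construct_recipes() -> dict[str, AssemblyRecipe]:
    """Recipes for the three expression constructs (per-plasmid motif plan)."""
    out = {"W4": W4_RECIPE, "4MBS": AssemblyRecipe("4MBS", MBS4_CORE_ITEMS)}
    for n_w4, name in ((1, "E2-13W4"), (2, "E1-W8"), (3, "E1-W12")):
        items = (("7His", 1), ("InitTag", 1))
        items += W4_RECIPE.items * n_w4
        items += (("RGD", 3), ("EmGFP", 1))
        out[name] = AssemblyRecipe(name, items, JunctionPolicy.GS_AT_TANDEM_JUNCTIONS)
    return out


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------

def assemble(
    recipe: AssemblyRecipe,
    catalog: Mapping[str, ProteinModule],
    motif_defs: Mapping[str, str] | None = None,
) -> DesignedConstruct:
    """Concatenate catalog modules per the recipe, tracking provenance spans.

    Under ``gly_ser_at_tandem_junctions``, a "GS" dipeptide (encoded by the
    BglII/BamHI hybrid site used for tandemization) is inserted between
    consecutive copies produced from a single recipe item with copy_count > 1.
    """
    recipe.validate(catalog)
    parts: list[str] = []
    spans: list[tuple[int, int, str]] = []
    pos = 0

    def _push(seq: str, label: str) -> None:
        nonlocal pos
        parts.append(seq)
        spans.append((pos, pos + len(seq), label))
        pos += len(seq)

    gs = recipe.junction_policy is JunctionPolicy.GS_AT_TANDEM_JUNCTIONS
    for mod_name, count in recipe.items:
        seq = catalog[mod_name].aa_sequence
        for i in range(count):
            if gs and i > 0:
                _push("GS", "junction")
            _push(seq, mod_name)

    construct = DesignedConstruct(recipe.name, "".join(parts), spans)
    construct.motif_counts = count_motifs(construct, motif_defs or DEFAULT_MOTIF_DEFS)
    return construct


# ---------------------------------------------------------------------------
# Motif counting
# ---------------------------------------------------------------------------

#: literal motifs; ELP is handled separately as the VPGXG pentapeptide pattern
DEFAULT_MOTIF_DEFS: dict[str, str] = {
    "MBS": MBS_SEQ,
    "F3": F3_SEQ,
    "RGD": RGD_CORE,
}

ELP_BLOCK_MODULES = ("E(Y)", "E", "Eend")


def _count_nonoverlapping(haystack: str, needle: str) -> int:
    count = start = 0
    while True:
        idx = haystack.find(needle, start)
        if idx < 0:
            return count
        count += 1
        start = idx + len(needle)


def _count_elp_pentapeptides(seq: str) -> int:
    """Non-overlapping VPGXG units, X any canonical residue except Pro."""
    count = i = 0
    n = len(seq)
    while i <= n - 5:
        if (
            seq[i] == "V" and seq[i + 1] == "P" and seq[i + 2] == "G"
            and seq[i + 4] == "G" and seq[i + 3] != "P"
        ):
            count += 1
            i += 5
        else:
            i += 1
    return count


def count_motifs(
    construct: DesignedConstruct | str,
    motif_defs: Mapping[str, str] | None = None,
) -> dict[str, int]:
    """Count non-overlapping motif occurrences in a construct.

    ELP repeats are reported in both printed conventions: ``ELP_units`` counts
    VPGXG pentapeptides; ``ELP_blocks`` counts E-type module spans (E(Y), E,
    Eend), and is only available when provenance spans exist.
    """
    if isinstance(construct, str):
        construct = DesignedConstruct("anonymous", construct)
    seq = construct.aa_sequence
    counts: dict[str, int] = {}
    for motif, literal in (motif_defs or DEFAULT_MOTIF_DEFS).items():
        counts[motif] = _count_nonoverlapping(seq, literal)
    counts["ELP_units"] = _count_elp_pentapeptides(seq)
    if construct.spans:
        counts["ELP_blocks"] = sum(
            construct.module_span_count(m) for m in ELP_BLOCK_MODULES
        )
    return counts


def effective_ligand_concentration(
    construct: DesignedConstruct,
    protein_conc_uM: float,
    motif: str,
    motif_defs: Mapping[str, str] | None = None,
) -> float:
    """Per-motif effective concentration: [protein] x (motif copies/molecule).

    Mirrors the bookkeeping used to compare constructs in cell-uptake assays,
    where the working concentration of RGD or F3 is the molar protein
    concentration multiplied by the motif copy number.
    """
    if protein_conc_uM < 0:
        raise ValueError("protein concentration must be >= 0")
    counts = construct.motif_counts or count_motifs(construct, motif_defs)
    copies = counts.get(motif, 0)
    if copies == 0:
        warnings.warn(f"motif {motif!r} absent from construct {construct.name!r}")
        return 0.0
    return protein_conc_uM * copies
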