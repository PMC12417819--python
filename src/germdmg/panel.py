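"""Curated cancer-predisposition gene panel with traffic-light labels.

A panel is the gene-level scaffold of the whole analysis: each entry carries
a curator-assigned clinical-relevance *traffic light* (green genes are
analysed, amber are of intermediate relevance, red are excluded), an
inheritance mode, a tumor-suppressor flag, a DNA-repair/signaling pathway
assignment, and a *dosage-sensitive exception* flag marking autosomal
recessive genes (MUTYH, CHEK2, Fanconi anemia genes) that are curated even
on a single germline hit.

Panels are plain tab-separated files (UTF-8, ``#`` comments, case-insensitive
enum tokens) with columns::

    gene  traffic_light  inheritance  tumor_suppressor  pathway  exception
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator


class PanelFormatError(ValueError):
    """Raised when a panel TSV violates the format contract."""


class PanelLookupError(KeyError):
    """Raised when a gene symbol is not present in a panel."""


class TrafficLight(str, enum.Enum):
    GREEN = "green"
    AMBER = "amber"
    RED = "red"


class Inheritance(str, enum.Enum):
    DOMINANT = "dominant"
    RECESSIVE = "recessive"
    X_LINKED = "x_linked"
    UNKNOWN = "unknown"


class Pathway(str, enum.Enum):
    """Pathway grouping used for germline panel genes."""

    HR = "HR"
    FA = "FA"
    MMR = "MMR"
    BER = "BER"
    MAPK_ERK = "MAPK_ERK"
    RTK = "RTK"
    PI3K_AKT_MTOR = "PI3K_AKT_mTOR"
    BMP = "BMP"
    METABOLISM = "metabolism"
    EPIGENETICS = "epigenetics"
    TRANSCRIPTION = "transcription"
    OTHER = "other"


_YES = {"yes", "y", "true", "1"}
_NO = {"no", "n", "false", "0"}

_COLUMNS = (
    "gene",
    "traffic_light",
    "inheritance",
    "tumor_suppressor",
    "pathway",
    "exception",
)


@dataclass(frozen=True)
class GenePanelEntry:
    """One curated gene with its clinical-relevance annotations."""

    gene_symbol: str
    traffic_light: TrafficLight
    inheritance: Inheritance
    is_tumor_suppressor: bool
    pathway: Pathway
    dosage_sensitive_exception: bool = False

    def __post_init__(self) -> None:
        if not self.gene_symbol:
            raise PanelFormatError("gene symbol must be non-empty")

    @property
    def excluded_from_analysis(self) -> bool:
        """Red-light genes stay in the panel but are excluded from analysis."""
        return self.traffic_light is TrafficLight.RED


class GenePanel:
    """A versioned collection of :class:`GenePanelEntry`, keyed by symbol."""

    def __init__(self, entries: Iterable[GenePanelEntry], version: str = "custom"):
        self.version = version
        self._entries: dict[str, GenePanelEntry] = {}
        for e in entries:
            if e.gene_symbol in self._entries:
                raise PanelFormatError(f"duplicate gene symbol: {e.gene_symbol}")
            self._entries[e.gene_symbol] = e

    def __len__(self) -> int:
        return len(self._entries)

    def __iter__(self) -> Iterator[GenePanelEntry]:
        return iter(self._entries.values())

    def __contains__(self, gene: str) -> bool:
        return gene in self._entries

    def entry(self, gene: str) -> GenePanelEntry:
        try:
            return self._entries[gene]
        except KeyError:
            raise PanelLookupError(f"gene not in panel: {gene}") from None

    def __getitem__(self, gene: str) -> GenePanelEntry:
        return self.entry(gene)

    def green_entries(self) -> list[GenePanelEntry]:
        return [e for e in self if e.traffic_light is TrafficLight.GREEN]


def pathway_of(panel: GenePanel, gene: str) -> Pathway:
    """Pathway label of ``gene`` in ``panel`` (lookup error if absent)."""
    return panel.entry(gene).pathway


def _parse_bool(token: str, row: int, col: str) -> bool:
    t = token.strip().lower()
    if t in _YES:
        return True
    if t in _NO:
        return False
    raise PanelFormatError(f"row {row}: bad {col} token {token!r}")


def _parse_enum(cls, token: str, row: int, col: str):
    t = token.strip()
    for member in cls:
        if member.value.lower() == t.lower():
            return member
    raise PanelFormatError(f"row {row}: unknown {col} token {token!r}")


def _parse_panel_lines(lines: Iterable[str], version: str) -> GenePanel:
    entries: list[GenePanelEntry] = []
    header: list[str] | None = None
    for i, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = [f.strip() for f in line.split("\t")]
        if header is None:
            header = [f.lower() for f in fields]
            missing = [c for c in _COLUMNS if c not in header]
            if missing:
                raise PanelFormatError(f"header missing columns: {missing}")
            continue
        row = dict(zip(header, fields))
        gene = row.get("gene", "")
        if not gene:
            raise PanelFormatError(f"row {i}: missing gene symbol")
        entries.append(
            GenePanelEntry(
                gene_symbol=gene,
                traffic_light=_parse_enum(TrafficLight, row["traffic_light"], i, "traffic_light"),
                inheritance=_parse_enum(Inheritance, row["inheritance"], i, "inheritance"),
                is_tumor_suppressor=_parse_bool(row["tumor_suppressor"], i, "tumor_suppressor"),
                pathway=_parse_enum(Pathway, row["pathway"], i, "pathway"),
                dosage_sensitive_exception=_parse_bool(row["exception"], i, "exception"),
            )
        )
    if header is None:
        raise PanelFormatError("panel file has no header row")
    return GenePanel(entries, version=version)


def load_gene_panel(path: str | Path) -> GenePanel:
    """Load a gene panel from a TSV file.

    Raises :class:`PanelFormatError` for a missing/duplicate gene symbol or
    an unknown enum token, naming the offending row.
    """
    p = Path(path)
    with p.open("r", encoding="utf-8") as fh:
        return _parse_panel_lines(fh, version=p.stem)


def write_gene_panel(panel: GenePanel, path: str | Path) -> None:
    """Write a panel back to TSV (round-trips through :func:`load_gene_panel`)."""
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("\t".join(_COLUMNS) + "\n")
        for e in panel:
            fh.write(
                "\t".join(
                    [
                        e.gene_symbol,
                        e.traffic_light.value,
                        e.inheritance.value,
                        "yes" if e.is_tumor_suppressor else "no",
                        e.pathway.value,
                        "yes" if e.dosage_sensitive_exception else "no",
                    ]
                )
                + "\n"
            )


# Default panel: a documented reconstruction covering the genes named in the
# cohort's reportable findings, plus MUTYH and TP53. The full curated
# 191-gene list is not public; users supply fuller panels via TSV.
# CHEK2 is grouped under HR and flagged dosage-sensitive, matching how the
# cohort analysis grouped it.
_DEFAULT_PANEL_TSV = """\
gene	traffic_light	inheritance	tumor_suppressor	pathway	exception
PALB2	green	dominant	yes	HR	no
BRCA1	green	dominant	yes	HR	no
BRCA2	green	dominant	yes	HR	no
CHEK2	green	dominant	yes	HR	yes
BRIP1	green	dominant	yes	HR	no
FANCE	green	recessive	yes	FA	yes
FANCD2	green	recessive	yes	FA	yes
FANCM	green	recessive	yes	FA	yes
SLX4	green	recessive	yes	FA	yes
PMS2	green	dominant	yes	MMR	no
MSH2	green	dominant	yes	MMR	no
MUTYH	green	recessive	yes	BER	yes
LZTR1	green	dominant	yes	MAPK_ERK	no
FGFR2	green	dominant	no	RTK	no
SDHA	green	dominant	yes	metabolism	no
MAX	green	dominant	yes	epigenetics	no
HOXB13	green	dominant	no	transcription	no
TP53	green	dominant	yes	other	no
"""


def default_panel() -> GenePanel:
    """The bundled default cancer-predisposition gene panel."""
    return _parse_panel_lines(_DEFAULT_PANEL_TSV.splitlines(), version="default-18")
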