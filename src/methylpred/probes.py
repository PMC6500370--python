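"""Probe-to-gene mapping and probe classification for 450K-style arrays.

A probe annotation row carries semicolon-joined gene symbols and region
groups in manifest convention (``UCSC_RefGene_Name`` / ``UCSC_RefGene_Group``).
Probes on the array but present in a user-supplied exclusion list — those
with potential SNP overlap or cross-hybridization — are classed ``s_and_c``;
everything else is a ``methylation`` probe, and "all probes" is their union.

The promoter region is taken as TSS1500 + TSS200 + 5'UTR + 1stExon and the
gene body as Body; 3'UTR probes belong to neither region subset.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

log = logging.getLogger(__name__)

__all__ = [
    "REGION_GROUPS",
    "PROMOTER_GROUPS",
    "BODY_GROUPS",
    "AnnotationParseError",
    "ProbeAnnotation",
    "ProbeClassification",
    "GeneProbe",
    "GeneProbeMap",
    "load_probe_annotation",
    "load_exclusion_list",
    "classify_probes",
    "build_gene_probe_map",
    "probes_for_gene",
]

REGION_GROUPS = ("TSS1500", "TSS200", "5'UTR", "1stExon", "Body", "3'UTR")
PROMOTER_GROUPS = frozenset({"TSS1500", "TSS200", "5'UTR", "1stExon"})
BODY_GROUPS = frozenset({"Body"})

_GROUP_ALIASES = {"5UTR": "5'UTR", "3UTR": "3'UTR"}

PROBE_SET_MODES = ("methylation", "s_and_c", "all")
REGION_MODES = ("all", "promoter", "body")


class AnnotationParseError(ValueError):
    """Malformed probe annotation row."""


@dataclass
class ProbeAnnotation:
    """One probe's gene assignments with aligned region groups."""

    probe_id: str
    gene_symbols: tuple[str, ...] = ()
    region_groups: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if len(self.gene_symbols) != len(self.region_groups):
            raise AnnotationParseError(
                f"probe {self.probe_id!r}: {len(self.gene_symbols)} genes but "
                f"{len(self.region_groups)} region groups"
            )
        groups = tuple(_GROUP_ALIASES.get(g, g) for g in self.region_groups)
        bad = [g for g in groups if g not in REGION_GROUPS]
        if bad:
            raise AnnotationParseError(
                f"probe {self.probe_id!r}: unknown region group {bad[0]!r}"
            )
        # dedupe (gene, group) pairs, order-preserving
        seen: set[tuple[str, str]] = set()
        genes, kept = [], []
        for g, r in zip(self.gene_symbols, groups):
            if (g, r) not in seen:
                seen.add((g, r))
                genes.append(g)
                kept.append(r)
        self.gene_symbols = tuple(genes)
        self.region_groups = tuple(kept)

    def groups_for_gene(self, gene: str) -> frozenset[str]:
        return frozenset(
            r for g, r in zip(self.gene_symbols, self.region_groups) if g == gene
        )


@dataclass
class ProbeClassification:
    """Partition of probes into methylation vs S&C (excluded) classes."""

    classes: dict[str, str]
    provenance: str | None = None

    def __getitem__(self, probe_id: str) -> str:
        return self.classes[probe_id]

    def probe_ids(self, probe_class: str) -> list[str]:
        return [p for p, c in self.classes.items() if c == probe_class]


@dataclass
class GeneProbe:
    """A probe's membership in one gene: region groups plus class."""

    probe_id: str
    groups: frozenset[str]
    probe_class: str


@dataclass
class GeneProbeMap:
    """gene symbol -> probes annotated to it, ascending by probe id."""

    genes: dict[str, list[GeneProbe]] = field(default_factory=dict)

    def __contains__(self, gene: str) -> bool:
        return gene in self.genes

    def gene_ids(self) -> list[str]:
        return list(self.genes)


def _split_field(raw: str) -> list[str]:
    raw = raw.strip().strip('"')
    if not raw:
        return []
    return [tok.strip() for tok in raw.split(";")]


def load_probe_annotation(path: str | Path) -> dict[str, ProbeAnnotation]:
    """Parse a manifest-like annotation table into per-probe annotations.

    Accepts CSV or TSV with columns for the probe id (``probe_id``,
    ``IlmnID`` or ``Name``), ``UCSC_RefGene_Name`` and ``UCSC_RefGene_Group``.
    Probes with an empty gene field are retained but map to no gene.
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    lines = [
        l for l in path.read_text().splitlines() if l.strip() and not l.startswith("#")
    ]
    if not lines:
        raise AnnotationParseError(f"{path}: empty annotation file")
    header = [h.strip().strip('"') for h in lines[0].split(sep)]
    lower = [h.lower() for h in header]

    def _col(*names: str) -> int:
        for name in names:
            if name.lower() in lower:
                return lower.index(name.lower())
        raise AnnotationParseError(f"{path}: missing column (tried {names})")

    i_probe = _col("probe_id", "IlmnID", "Name", "ID")
    i_gene = _col("UCSC_RefGene_Name", "gene", "gene_symbols")
    i_group = _col("UCSC_RefGene_Group", "region_group", "region_groups")

    annotations: dict[str, ProbeAnnotation] = {}
    for line in lines[1:]:
        fields = [f.strip().strip('"') for f in line.split(sep)]
        probe = fields[i_probe]
        genes = _split_field(fields[i_gene]) if i_gene < len(fields) else []
        groups = _split_field(fields[i_group]) if i_group < len(fields) else []
        annotations[probe] = ProbeAnnotation(probe, tuple(genes), tuple(groups))
    return annotations


def load_exclusion_list(path: str | Path) -> set[str]:
    """One probe id per line; blank lines and '#' comments ignored."""
    out = set()
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            out.add(line)
    return out


def classify_probes(
    probe_ids, exclusion_list: set[str], provenance: str | None = None
) -> ProbeClassification:
    """Excluded probes become ``s_and_c``; the rest are ``methylation``.

    With an empty exclusion list every probe is a methylation probe, in
    which case "all probes" coincides with the methylation set.
    """
    classes = {
        p: ("s_and_c" if p in exclusion_list else "methylation") for p in probe_ids
    }
    return ProbeClassification(classes, provenance)


def build_gene_probe_map(
    annotations: dict[str, ProbeAnnotation],
    classification: ProbeClassification,
    probe_ids,
) -> GeneProbeMap:
    """Invert per-probe annotations into a per-gene probe list.

    Only probes present in ``probe_ids`` (the methylation matrix) are kept;
    a multi-gene probe contributes to every gene it annotates.
    """
    present = set(probe_ids)
    genes: dict[str, list[GeneProbe]] = {}
    for probe_id in sorted(present):
        ann = annotations.get(probe_id)
        if ann is None:
            continue
        cls = classification.classes.get(probe_id, "methylation")
        for gene in dict.fromkeys(ann.gene_symbols):
            genes.setdefault(gene, []).append(
                GeneProbe(probe_id, ann.groups_for_gene(gene), cls)
            )
    return GeneProbeMap(genes)


def probes_for_gene(
    gene: str,
    gene_map: GeneProbeMap,
    probe_set_mode: str = "all",
    region_mode: str = "all",
) -> list[str]:
    """Ordered probe ids for a gene after class and region filtering.

    ``probe_set_mode`` selects methylation probes, S&C probes or their union;
    ``region_mode`` selects promoter (TSS1500/TSS200/5'UTR/1stExon), gene
    body (Body) or all groups.  A probe annotated to the gene under any
    qualifying group is included once.  An unknown gene yields an empty list
    with a warning rather than an error.
    """
    if probe_set_mode not in PROBE_SET_MODES:
        raise ValueError(f"unknown probe_set_mode {probe_set_mode!r}")
    if region_mode not in REGION_MODES:
        raise ValueError(f"unknown region_mode {region_mode!r}")
    if gene not in gene_map:
        log.warning("gene %r not in probe map", gene)
        return []
    out = []
    for gp in gene_map.genes[gene]:
        if probe_set_mode != "all" and gp.probe_class != probe_set_mode:
            continue
        if region_mode == "promoter" and not (gp.groups & PROMOTER_GROUPS):
            continue
        if region_mode == "body" and not (gp.groups & BODY_GROUPS):
            continue
        out.append(gp.probe_id)
    return out
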