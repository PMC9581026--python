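"""Input/output for every external format the pipeline touches.

All science-free plumbing lives here: expression matrices with phenotype
labels, interaction edge lists (plain two-column TSV or the BioGRID
TAB-delimited dialect), GMT gene-set collections, drug-gene tables,
clinical survival tables, and Cytoscape-loadable module exports (SIF and
GraphML).

Gene identity is the plain string symbol, case-sensitive, with no alias
resolution: callers must harmonize identifiers upstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

NORMAL = "normal"
TUMOR = "tumor"
PHENOTYPES = (NORMAL, TUMOR)


class FormatError(ValueError):
    """A file does not conform to its declared format."""


# ---------------------------------------------------------------------------
# Domain containers
# ---------------------------------------------------------------------------

@dataclass
class ExpressionDataset:
    """A genes x samples expression matrix with a binary phenotype per sample.

    Parameters
    ----------
    gene_ids
        Unique gene symbols, one per matrix row.
    sample_ids
        Unique sample identifiers, one per matrix column.
    values
        Non-negative expression values (intensities or FPKM), shape
        ``(len(gene_ids), len(sample_ids))``.
    phenotype
        Per-sample label, each ``"normal"`` or ``"tumor"``.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    phenotype: list[str]

    def __post_init__(self) -> None:
        self.gene_ids = list(self.gene_ids)
        self.sample_ids = list(self.sample_ids)
        self.phenotype = list(self.phenotype)
        self.values = np.asarray(self.values, dtype=float)
        if len(set(self.gene_ids)) != len(self.gene_ids):
            dupes = sorted({g for g in self.gene_ids if self.gene_ids.count(g) > 1})
            raise FormatError(f"duplicate gene id(s): {', '.join(dupes)}")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise FormatError("duplicate sample ids")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise FormatError(
                f"value matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(self.phenotype) != len(self.sample_ids):
            raise FormatError("one phenotype label required per sample")
        bad = sorted(set(self.phenotype) - set(PHENOTYPES))
        if bad:
            raise FormatError(f"unknown phenotype label(s): {', '.join(bad)}")
        if np.any(~np.isfinite(self.values)) or np.any(self.values < 0):
            raise FormatError("expression values must be finite and non-negative")
        for ph in PHENOTYPES:
            if self.phenotype.count(ph) < 2:
                raise FormatError(f"need at least 2 '{ph}' samples")

    @property
    def n_normal(self) -> int:
        return self.phenotype.count(NORMAL)

    @property
    def n_tumor(self) -> int:
        return self.phenotype.count(TUMOR)

    @property
    def phenotype_mask(self) -> np.ndarray:
        """Boolean array, True where the sample is a tumor sample."""
        return np.array([p == TUMOR for p in self.phenotype])

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_ids)}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)


def canonical_edge(a: str, b: str) -> tuple[str, str]:
    """Order an unordered gene pair lexicographically."""
    return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class InteractionNetwork:
    """An undirected PPI network as a set of canonical gene-symbol pairs."""

    edges: frozenset[tuple[str, str]]

    @classmethod
    def from_pairs(cls, pairs) -> "InteractionNetwork":
        """Canonicalize, deduplicate, and drop self-loops (logged)."""
        edges = set()
        n_loops = 0
        for a, b in pairs:
            if a == b:
                n_loops += 1
                continue
            edges.add(canonical_edge(a, b))
        if n_loops:
            logger.warning("dropped %d self-loop(s)", n_loops)
        return cls(frozenset(edges))

    def nodes(self) -> set[str]:
        return {g for e in self.edges for g in e}

    def __len__(self) -> int:
        return len(self.edges)


@dataclass(frozen=True)
class DrugGeneTable:
    """A set of (drug_id, gene_symbol) interaction records."""

    records: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        for drug, gene in self.records:
            if not drug or not gene:
                raise FormatError("empty drug or gene identifier")

    def gene_sets(self) -> dict[str, set[str]]:
        """Per-drug target gene sets."""
        out: dict[str, set[str]] = {}
        for drug, gene in self.records:
            out.setdefault(drug, set()).add(gene)
        return out

    def universe(self) -> set[str]:
        """All genes occurring anywhere in the table."""
        return {gene for _, gene in self.records}


@dataclass
class ClinicalTable:
    """Per-sample follow-up time and event status (1=death, 0=censored)."""

    sample_ids: list[str]
    time: np.ndarray
    event: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = list(self.sample_ids)
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise FormatError("duplicate sample ids in clinical table")
        if not (len(self.sample_ids) == len(self.time) == len(self.event)):
            raise FormatError("clinical table columns have unequal lengths")
        if np.any(self.time < 0) or np.any(~np.isfinite(self.time)):
            raise FormatError("survival times must be finite and >= 0")
        if not set(np.unique(self.event)).issubset({0, 1}):
            raise FormatError("event status must be 0 or 1")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"sample": self.sample_ids, "time": self.time, "event": self.event}
        )

    def subset(self, sample_ids: list[str]) -> "ClinicalTable":
        idx = {s: i for i, s in enumerate(self.sample_ids)}
        keep = [idx[s] for s in sample_ids if s in idx]
        return ClinicalTable(
            [self.sample_ids[i] for i in keep], self.time[keep], self.event[keep]
        )


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

def read_expression(path_matrix, path_labels) -> ExpressionDataset:
    """Read a genes x samples TSV matrix plus a sample -> phenotype label file.

    The matrix has a header row of sample ids and gene symbols in the first
    column. The label file maps each sample id to ``normal`` or ``tumor``
    (two tab-separated columns, optional header). Genes with any missing
    value are dropped with a warning: the downstream state model needs
    complete rows.
    """
    df = pd.read_csv(path_matrix, sep="\t", index_col=0, dtype=str)
    genes = [str(g) for g in df.index]
    dupes = sorted({g for g in genes if genes.count(g) > 1})
    if dupes:
        raise FormatError(f"duplicate gene id(s) in matrix: {', '.join(dupes)}")
    samples = [str(c) for c in df.columns]

    values = np.full(df.shape, np.nan)
    for j, col in enumerate(df.columns):
        for i, raw in enumerate(df[col]):
            if raw is None or (isinstance(raw, float) and np.isnan(raw)):
                continue
            s = str(raw).strip()
            if s == "" or s.upper() in {"NA", "NAN"}:
                continue
            try:
                values[i, j] = float(s)
            except ValueError:
                raise FormatError(
                    f"non-numeric value {s!r} at gene {genes[i]!r}, "
                    f"sample {samples[j]!r}"
                ) from None

    labels = _read_labels(path_labels)
    missing = [s for s in samples if s not in labels]
    if missing:
        raise FormatError(f"sample(s) missing from label file: {', '.join(missing)}")
    phenotype = [labels[s] for s in samples]

    incomplete = np.isnan(values).any(axis=1)
    if incomplete.any():
        dropped = [g for g, bad in zip(genes, incomplete) if bad]
        logger.warning(
            "dropped %d gene(s) with missing values: %s",
            len(dropped), ", ".join(dropped[:10]),
        )
        keep = ~incomplete
        genes = [g for g, ok in zip(genes, keep) if ok]
        values = values[keep]
    return ExpressionDataset(genes, samples, values, phenotype)


def _read_labels(path) -> dict[str, str]:
    labels: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(f"{path}:{lineno}: expected 2 tab-separated fields")
            sample, label = parts[0].strip(), parts[1].strip()
            if lineno == 1 and label not in PHENOTYPES:
                continue  # header row
            if label not in PHENOTYPES:
                raise FormatError(
                    f"{path}:{lineno}: phenotype must be one of {PHENOTYPES}, got {label!r}"
                )
            labels[sample] = label
    return labels


def write_expression(ds: ExpressionDataset, path_matrix, path_labels) -> None:
    ds.to_frame().to_csv(path_matrix, sep="\t", index_label="gene")
    with open(path_labels, "w") as fh:
        fh.write("sample\tphenotype\n")
        for s, p in zip(ds.sample_ids, ds.phenotype):
            fh.write(f"{s}\t{p}\n")


# ---------------------------------------------------------------------------
# Interaction networks
# ---------------------------------------------------------------------------

#: Columns of the BioGRID TAB dialect we rely on.
_BIOGRID_A = "Official Symbol Interactor A"
_BIOGRID_B = "Official Symbol Interactor B"
_BIOGRID_TYPE = "Experimental System Type"


def read_network(path, dialect: str = "simple") -> InteractionNetwork:
    """Read an interaction network.

    ``dialect="simple"`` expects two whitespace/tab-separated gene symbols
    per line (``#`` comments allowed). ``dialect="biogrid-tab"`` expects the
    BioGRID TAB format and keeps only rows whose experimental system type is
    ``physical``, matching the physically detected subset of the interactome.
    """
    if dialect == "simple":
        pairs = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split()
                if len(parts) != 2:
                    raise FormatError(
                        f"{path}:{lineno}: expected 2 fields, got {len(parts)}"
                    )
                pairs.append((parts[0], parts[1]))
        return InteractionNetwork.from_pairs(pairs)
    if dialect == "biogrid-tab":
        df = pd.read_csv(path, sep="\t", dtype=str)
        for col in (_BIOGRID_A, _BIOGRID_B, _BIOGRID_TYPE):
            if col not in df.columns:
                raise FormatError(f"{path}: missing BioGRID column {col!r}")
        phys = df[df[_BIOGRID_TYPE].str.lower() == "physical"]
        return InteractionNetwork.from_pairs(
            zip(phys[_BIOGRID_A].astype(str), phys[_BIOGRID_B].astype(str))
        )
    raise ValueError(f"unknown network dialect {dialect!r}")


def write_network(net: InteractionNetwork, path) -> None:
    with open(path, "w") as fh:
        for a, b in sorted(net.edges):
            fh.write(f"{a}\t{b}\n")


def filter_network_to_expression(
    net: InteractionNetwork, ds: ExpressionDataset
) -> InteractionNetwork:
    """Keep only edges whose both endpoints are measured in the dataset."""
    genes = set(ds.gene_ids)
    kept = frozenset(e for e in net.edges if e[0] in genes and e[1] in genes)
    if len(kept) < len(net.edges):
        logger.info(
            "network filtered to expression: %d of %d edges kept",
            len(kept), len(net.edges),
        )
    return InteractionNetwork(kept)


# ---------------------------------------------------------------------------
# Gene sets, drug tables, clinical tables
# ---------------------------------------------------------------------------

def read_gmt(path) -> dict[str, set[str]]:
    """Read a GMT collection: name, description, tab-separated members."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line needs name, description and "
                    f">=1 member"
                )
            name = parts[0]
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = {m for m in parts[2:] if m}
    return sets


def write_gmt(sets: dict[str, set[str]], path, description: str = "") -> None:
    with open(path, "w") as fh:
        for name in sorted(sets):
            members = "\t".join(sorted(sets[name]))
            fh.write(f"{name}\t{description}\t{members}\n")


def read_drug_gene_table(path) -> DrugGeneTable:
    """Read a two-column (drug, gene) TSV; an optional header is skipped."""
    records = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(f"{path}:{lineno}: expected 2 tab-separated fields")
            drug, gene = parts[0].strip(), parts[1].strip()
            if lineno == 1 and (drug.lower(), gene.lower()) == ("drug", "gene"):
                continue
            if not drug or not gene:
                raise FormatError(f"{path}:{lineno}: empty drug or gene identifier")
            records.add((drug, gene))
    return DrugGeneTable(frozenset(records))


def write_drug_gene_table(table: DrugGeneTable, path) -> None:
    with open(path, "w") as fh:
        fh.write("drug\tgene\n")
        for drug, gene in sorted(table.records):
            fh.write(f"{drug}\t{gene}\n")


def read_clinical(path) -> ClinicalTable:
    """Read a clinical TSV with columns sample, time, event (header required)."""
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    cols = {c.lower(): c for c in df.columns}
    try:
        sample_col = cols.get("sample") or cols["sample_id"]
        time_col = cols["time"]
        event_col = cols["event"]
    except KeyError as exc:
        raise FormatError(
            f"{path}: clinical table needs 'sample', 'time' and 'event' columns"
        ) from exc
    return ClinicalTable(
        df[sample_col].astype(str).tolist(),
        df[time_col].to_numpy(),
        df[event_col].to_numpy(),
    )


def write_clinical(table: ClinicalTable, path) -> None:
    table.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Module exports (Cytoscape SIF / GraphML)
# ---------------------------------------------------------------------------

SIF_RELATION = "interacts"


def write_module_sif(hub: str, edges, path) -> None:
    """Write one hub-star module as SIF ``hub interacts member`` triples."""
    with open(path, "w") as fh:
        for a, b in sorted(edges):
            member = b if a == hub else a
            fh.write(f"{hub}\t{SIF_RELATION}\t{member}\n")


def read_module_sif(path) -> tuple[str, frozenset[tuple[str, str]]]:
    """Read a hub-star SIF back into (hub, canonical edge set)."""
    edges = set()
    hub = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 3 or parts[1] != SIF_RELATION:
                raise FormatError(f"{path}:{lineno}: malformed SIF triple")
            if hub is None:
                hub = parts[0]
            elif hub != parts[0]:
                raise FormatError(f"{path}:{lineno}: more than one hub in SIF")
            edges.add(canonical_edge(parts[0], parts[2]))
    if hub is None:
        raise FormatError(f"{path}: empty SIF module")
    return hub, frozenset(edges)


def write_module_graphml(hub: str, edges, directions, path) -> None:
    g = nx.Graph()
    g.add_node(hub, role="hub")
    for e in sorted(edges):
        member = e[1] if e[0] == hub else e[0]
        g.add_node(member, role="member")
        dirs = directions.get(e) if directions else None
        g.add_edge(e[0], e[1], direction=",".join(sorted(dirs)) if dirs else "")
    nx.write_graphml(g, path)


def write_modules(catalog, directory, formats=("sif", "graphml")) -> list[Path]:
    """Export every module of a catalog; returns the paths written."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for name, module in sorted(catalog.modules.items()):
        if "sif" in formats:
            p = directory / f"{name}.sif"
            write_module_sif(module.hub, module.edges, p)
            written.append(p)
        if "graphml" in formats:
            p = directory / f"{name}.graphml"
            write_module_graphml(module.hub, module.edges, module.directions, p)
            written.append(p)
    return written
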