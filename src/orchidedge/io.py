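"""Readers and writers for the pipeline's interchange formats.

The pipeline touches four kinds of files, all plain text:

* rooted, time-calibrated phylogenies in Newick (branch lengths in Myr);
* per-marker multiple sequence alignments in FASTA, with a separate
  comma-delimited accession-to-species map;
* a comma-delimited assessment table holding, per taxon, Red List
  categories at two scopes (regional ``hk`` and national ``cn``) and
  four coded traits (habit, habitat membership, mating system, trade);
* comma-delimited result tables.

Taxon labels are canonicalised on input: surrounding whitespace is
trimmed and internal runs of spaces/underscores collapse to a single
underscore, so trees written by software that swaps spaces for
underscores still join against the assessment table.
"""

from __future__ import annotations

import io as _stdio
import re
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Mapping

import dendropy
import numpy as np
import pandas as pd
from Bio import SeqIO
from dendropy.utility.error import DataParseError

from .errors import AlignmentError, FormatError, ValidationError

__all__ = [
    "CATEGORIES",
    "SCOPE_COLUMNS",
    "Phylogeny",
    "AssessmentTable",
    "MarkerAlignment",
    "normalize_label",
    "read_newick",
    "write_newick",
    "read_fasta_alignment",
    "read_species_map",
    "read_assessments",
    "write_assessments",
]

#: Closed Red List vocabulary. "NA" marks a taxon without an assessment
#: at that scope; blank cells are read as NA.
CATEGORIES = ("LC", "NT", "VU", "EN", "CR", "RE", "EW", "DD", "NE", "NA")

#: Assessment scopes and the table columns that hold them.
SCOPE_COLUMNS = {"hk": "category_hk", "cn": "category_cn"}

_LABEL_RUNS = re.compile(r"[ _]+")


def normalize_label(label: str) -> str:
    """Canonical taxon label: trimmed, space/underscore runs -> ``_``."""
    return _LABEL_RUNS.sub("_", label.strip())


# ---------------------------------------------------------------------------
# Phylogeny
# ---------------------------------------------------------------------------


class Phylogeny:
    """A rooted tree with branch lengths, wrapping a :class:`dendropy.Tree`.

    Invariants enforced at construction: at least two tips; tip labels
    unique and non-empty (after canonicalisation); every non-root edge
    carries a finite, non-negative length.  A root edge length, if
    present in the source, is preserved for round-tripping but excluded
    from every metric.
    """

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        self._validate()
        self._arrays = None

    # -- validation --------------------------------------------------------

    def _validate(self) -> None:
        leaves = list(self._tree.leaf_node_iter())
        if len(leaves) < 2:
            raise ValidationError(
                f"a phylogeny needs at least 2 tips, got {len(leaves)}"
            )
        labels = []
        for leaf in leaves:
            raw = leaf.taxon.label if leaf.taxon is not None else leaf.label
            if raw is None or not raw.strip():
                raise ValidationError("empty tip label")
            labels.append(normalize_label(raw))
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise ValidationError(f"duplicate tip labels: {', '.join(dupes)}")
        for node in self._tree.preorder_node_iter():
            if node.parent_node is None:
                continue
            length = node.edge.length
            if length is None or not np.isfinite(length) or length < 0:
                raise ValidationError(
                    f"edge above {node.taxon.label if node.taxon else 'internal node'} "
                    f"has invalid length {length!r}"
                )

    # -- basic accessors ---------------------------------------------------

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree

    @property
    def tip_labels(self) -> list[str]:
        out = []
        for leaf in self._tree.leaf_node_iter():
            raw = leaf.taxon.label if leaf.taxon is not None else leaf.label
            out.append(normalize_label(raw))
        return out

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    # -- index arrays for the metric layer ---------------------------------

    def edge_arrays(self):
        """Flat arrays describing the tree, cached.

        Returns a dict with

        ``tips``
            tip labels in a fixed traversal order;
        ``tbl``
            terminal branch length per tip (Myr);
        ``depth``
            root-to-tip path length per tip, root edge excluded;
        ``internal_edges``
            list of ``(length, desc_idx)`` for every internal non-root
            edge, ``desc_idx`` the integer indices of descendant tips.
        """
        if self._arrays is not None:
            return self._arrays
        tips = self.tip_labels
        index = {label: i for i, label in enumerate(tips)}
        n = len(tips)
        tbl = np.zeros(n)
        depth = np.zeros(n)
        internal = []
        desc: dict[int, list[int]] = {}
        for node in self._tree.postorder_node_iter():
            if node.is_leaf():
                raw = node.taxon.label if node.taxon is not None else node.label
                desc[id(node)] = [index[normalize_label(raw)]]
            else:
                ids: list[int] = []
                for child in node.child_nodes():
                    ids.extend(desc[id(child)])
                desc[id(node)] = ids
            if node.parent_node is None:
                continue  # root edge excluded from all metrics
            length = float(node.edge.length)
            idx = desc[id(node)]
            if node.is_leaf():
                tbl[idx[0]] = length
            else:
                internal.append((length, np.asarray(idx, dtype=np.intp)))
            depth[np.asarray(idx, dtype=np.intp)] += length
        self._arrays = {
            "tips": tips,
            "tbl": tbl,
            "depth": depth,
            "internal_edges": internal,
        }
        return self._arrays


def read_newick(source: str | Path | IO[str]) -> Phylogeny:
    """Parse a rooted Newick tree with branch lengths.

    ``source`` may be a Newick string, a path, or an open text stream.
    Quoted labels and scientific-notation lengths are accepted; an
    optional root edge length is kept but never enters any metric.
    """
    text = _read_text(source)
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except DataParseError as exc:
        name = type(exc).__name__
        if "Duplicate" in name:
            raise ValidationError(f"duplicate tip label in Newick input: {exc}") from exc
        line = getattr(exc, "line_num", "?")
        col = getattr(exc, "col_num", "?")
        raise FormatError(
            f"malformed Newick at line {line}, column {col}: {exc}"
        ) from exc
    return Phylogeny(tree)


def write_newick(phylogeny: Phylogeny, path: str | Path | None = None) -> str:
    """Serialise to Newick; returns the string and optionally writes it."""
    text = phylogeny.dendropy_tree.as_string(
        schema="newick", suppress_rooting=True, unquoted_underscores=True
    )
    if path is not None:
        Path(path).write_text(text)
    return text


# ---------------------------------------------------------------------------
# Alignments
# ---------------------------------------------------------------------------


@dataclass
class MarkerAlignment:
    """An aligned set of accessions for one barcode marker.

    ``matrix`` holds the upper-cased alignment as single bytes, one row
    per accession; every accession maps to exactly one species label.
    """

    marker: str
    accessions: list[str]
    species: list[str]
    matrix: np.ndarray  # shape (n_accessions, length), dtype 'S1'

    def __post_init__(self) -> None:
        if self.matrix.ndim != 2 or self.matrix.shape[0] != len(self.accessions):
            raise ValidationError("alignment matrix shape does not match accessions")
        if len(self.species) != len(self.accessions):
            raise ValidationError("species list does not match accessions")

    @property
    def length(self) -> int:
        return int(self.matrix.shape[1])

    @property
    def n_accessions(self) -> int:
        return len(self.accessions)

    def sequence(self, i: int) -> str:
        return self.matrix[i].tobytes().decode("ascii")

    def to_fasta(self, path: str | Path | None = None) -> str:
        records = []
        for i, acc in enumerate(self.accessions):
            records.append(f">{acc}\n{self.sequence(i)}\n")
        text = "".join(records)
        if path is not None:
            Path(path).write_text(text)
        return text

    def species_map_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"accession": self.accessions, "species": self.species})


def read_species_map(source: str | Path | IO[str]) -> dict[str, str]:
    """Read a two-column ``accession,species`` CSV into a dict."""
    df = pd.read_csv(_as_handle(source), dtype=str, keep_default_na=False)
    for col in ("accession", "species"):
        if col not in df.columns:
            raise FormatError(f"species map is missing required column '{col}'")
    if df["accession"].duplicated().any():
        dupes = sorted(df.loc[df["accession"].duplicated(), "accession"])
        raise ValidationError(f"duplicate accessions in species map: {dupes}")
    return {
        acc.strip(): normalize_label(sp)
        for acc, sp in zip(df["accession"], df["species"])
    }


def read_fasta_alignment(
    source: str | Path | IO[str],
    species_map: Mapping[str, str] | str | Path,
    marker: str = "marker",
) -> MarkerAlignment:
    """Read an aligned FASTA; every accession must appear in the map.

    Sequences are case-folded to upper; ragged lengths raise
    :class:`AlignmentError`, an accession absent from the map raises
    :class:`ValidationError`.
    """
    if not isinstance(species_map, Mapping):
        species_map = read_species_map(species_map)
    records = list(SeqIO.parse(_as_handle(source), "fasta"))
    if not records:
        raise FormatError("no FASTA records found")
    lengths = {len(rec.seq) for rec in records}
    if len(lengths) != 1:
        raise AlignmentError(
            f"ragged alignment: sequence lengths {sorted(lengths)} differ"
        )
    accessions, species, rows = [], [], []
    for rec in records:
        acc = rec.id.strip()
        if acc not in species_map:
            raise ValidationError(f"accession '{acc}' missing from species map")
        accessions.append(acc)
        species.append(normalize_label(species_map[acc]))
        rows.append(np.frombuffer(str(rec.seq).upper().encode("ascii"), dtype="S1"))
    return MarkerAlignment(
        marker=marker,
        accessions=accessions,
        species=species,
        matrix=np.vstack(rows),
    )


# ---------------------------------------------------------------------------
# Assessment / trait tables
# ---------------------------------------------------------------------------

_ASSESSMENT_COLUMNS = ("taxon", "hk", "cn", "habit", "habitats", "mating", "trade")


@dataclass
class AssessmentTable:
    """Per-taxon Red List categories (two scopes) and coded traits.

    Columns of the backing frame (indexed by canonical taxon label):

    ``category_hk``, ``category_cn``
        Red List category at the regional (Hong Kong) and national
        (China) scope, from the closed vocabulary in :data:`CATEGORIES`.
    ``habit``
        1 = epiphyte/lithophyte, 2 = terrestrial, NaN = unknown.
    ``habitats``
        frozenset of habitat-type names the taxon occupies.
    ``mating``
        1 = selfing, 2 = outcrossing, NaN = unknown.
    ``trade``
        0 = untraded, 1 = ornamental, 2 = medicinal, 3 = both.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        if self.df.index.has_duplicates:
            dupes = sorted(self.df.index[self.df.index.duplicated()])
            raise ValidationError(f"duplicate taxa in assessment table: {dupes}")
        for col in SCOPE_COLUMNS.values():
            bad = set(self.df[col]) - set(CATEGORIES)
            if bad:
                raise ValidationError(
                    f"unknown Red List categories in {col}: {sorted(bad)}"
                )

    @property
    def taxa(self) -> list[str]:
        return list(self.df.index)

    def categories(self, scope: str) -> pd.Series:
        return self.df[_scope_column(scope)]

    def category(self, taxon: str, scope: str) -> str:
        taxon = normalize_label(taxon)
        if taxon not in self.df.index:
            raise ValidationError(f"taxon '{taxon}' not in assessment table")
        return self.df.at[taxon, _scope_column(scope)]


def _scope_column(scope: str) -> str:
    try:
        return SCOPE_COLUMNS[scope]
    except KeyError:
        raise ValidationError(
            f"unknown scope '{scope}'; expected one of {sorted(SCOPE_COLUMNS)}"
        ) from None


def read_assessments(source: str | Path | IO[str]) -> AssessmentTable:
    """Read the assessment/trait CSV.

    Header must name ``taxon,hk,cn,habit,habitats,mating,trade``.
    Blank category cells become NA; unknown category tokens are rejected
    with the offending row named.  Habitat membership is a
    semicolon-joined list of habitat-type names in one cell.
    """
    raw = pd.read_csv(_as_handle(source), dtype=str, keep_default_na=False)
    missing = [c for c in _ASSESSMENT_COLUMNS if c not in raw.columns]
    if missing:
        raise FormatError(f"assessment table is missing columns: {missing}")
    taxa, rows = [], []
    for pos, row in raw.iterrows():
        taxon = normalize_label(row["taxon"])
        if not taxon:
            raise ValidationError(f"row {pos + 2}: empty taxon label")
        cats = {}
        for scope, col in SCOPE_COLUMNS.items():
            token = row[scope].strip().upper()
            if not token:
                token = "NA"
            if token not in CATEGORIES:
                raise ValidationError(
                    f"row {pos + 2} (taxon '{taxon}'): unknown category "
                    f"'{row[scope]}' in scope '{scope}'"
                )
            cats[col] = token
        habitats = frozenset(
            h.strip() for h in row["habitats"].split(";") if h.strip()
        )
        taxa.append(taxon)
        rows.append(
            {
                **cats,
                "habit": _parse_code(row["habit"], {1, 2}, taxon, "habit", pos),
                "habitats": habitats,
                "mating": _parse_code(row["mating"], {1, 2}, taxon, "mating", pos),
                "trade": _parse_trade(row["trade"], taxon, pos),
            }
        )
    df = pd.DataFrame(rows, index=pd.Index(taxa, name="taxon"))
    return AssessmentTable(df)


def _parse_code(token: str, allowed: set[int], taxon: str, name: str, pos) -> float:
    token = token.strip()
    if not token:
        return float("nan")
    try:
        value = int(token)
    except ValueError:
        value = -1
    if value not in allowed:
        raise ValidationError(
            f"row {pos + 2} (taxon '{taxon}'): invalid {name} code '{token}'"
        )
    return float(value)


def _parse_trade(token: str, taxon: str, pos) -> int:
    token = token.strip()
    if not token:
        return 0
    try:
        value = int(token)
    except ValueError:
        value = -1
    if value not in {0, 1, 2, 3}:
        raise ValidationError(
            f"row {pos + 2} (taxon '{taxon}'): invalid trade code '{token}'"
        )
    return value


def write_assessments(table: AssessmentTable, path: str | Path | None = None) -> str:
    """Serialise an :class:`AssessmentTable` back to its CSV schema."""
    out = pd.DataFrame(
        {
            "taxon": table.df.index,
            "hk": table.df["category_hk"].values,
            "cn": table.df["category_cn"].values,
            "habit": [_fmt_code(v) for v in table.df["habit"]],
            "habitats": [";".join(sorted(h)) for h in table.df["habitats"]],
            "mating": [_fmt_code(v) for v in table.df["mating"]],
            "trade": table.df["trade"].values,
        }
    )
    text = out.to_csv(index=False)
    if path is not None:
        Path(path).write_text(text)
    return text


def _fmt_code(value: float) -> str:
    return "" if pd.isna(value) else str(int(value))


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


def _read_text(source) -> str:
    if hasattr(source, "read"):
        return source.read()
    if isinstance(source, Path):
        return source.read_text()
    if isinstance(source, str):
        # a short string that exists on disk is a path, otherwise it is data
        try:
            if len(source) < 4096 and Path(source).exists():
                return Path(source).read_text()
        except OSError:
            pass
        return source
    raise TypeError(f"cannot read from {type(source)!r}")


def _as_handle(source):
    if hasattr(source, "read"):
        return source
    if isinstance(source, Path):
        return str(source)
    if isinstance(source, str):
        try:
            if len(source) < 4096 and Path(source).exists():
                return source
        except OSError:
            pass
        if "\n" in source or "," in source or source.startswith(">"):
            return _stdio.StringIO(source)
        return source
    raise TypeError(f"cannot read from {type(source)!r}")
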