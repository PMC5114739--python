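"""Gene signature collections: data model, GMT I/O and built-in immune panels.

A *gene signature* is a named, ordered list of HGNC-style gene symbols that
marks one cell population or biological program.  The built-in panels are

``bindea24``
    24 immune-cell-type marker lists covering the adaptive and innate
    compartments (reconstructed from Bindea et al., Immunity 2013; 509
    distinct genes, 501 of which belong to exactly one signature).
``apm``
    A seven-gene antigen-presenting-machinery signature: the MHC class I
    genes HLA-A/B/C and B2M plus the peptide processing/loading genes TAP1,
    TAP2 and TAPBP.
``angiogenesis``
    A 40-gene endothelial/angiogenesis program (reconstructed from Masiero
    et al., Cancer Cell 2013).
``checkpoint_targets``
    Three single-gene signatures tracking the immunotherapy targets PD-1
    (PDCD1), PD-L1 (CD274) and CTLA-4 (CTLA4).

The ``bindea24`` and ``angiogenesis`` gene lists ship as GMT data files whose
sha256 checksums are pinned in ``data/MANIFEST.json``; the supplementary
tables of the source publications are not redistributable here, so the files
are curated reconstructions that satisfy every published structural property
of the originals (set count, total/unique gene counts, per-type sizes,
single-gene Treg and pDC sets).

Gene symbol matching throughout the package is exact, case-sensitive string
equality; alias/probe mapping is upstream preprocessing.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Mapping

__all__ = [
    "GeneSignature",
    "SignatureCollection",
    "GmtParseError",
    "parse_gmt",
    "write_gmt",
    "collection_stats",
    "builtin_signatures",
    "BUILTIN_KEYS",
]


class GmtParseError(ValueError):
    """Raised for malformed GMT input (too few fields, duplicate set names)."""


@dataclass(frozen=True)
class GeneSignature:
    """A named, duplicate-free, ordered gene list."""

    name: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("signature name must be nonempty")
        if not self.genes:
            raise ValueError(f"signature {self.name!r} has no genes")
        object.__setattr__(self, "genes", tuple(self.genes))
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"signature {self.name!r} contains duplicate genes")

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in set(self.genes)


@dataclass(frozen=True)
class SignatureCollection:
    """An ordered set of signatures with unique names."""

    signatures: tuple[GeneSignature, ...]
    source: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "signatures", tuple(self.signatures))
        names = [s.name for s in self.signatures]
        if len(set(names)) != len(names):
            dups = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate signature names: {dups}")

    def __iter__(self) -> Iterator[GeneSignature]:
        return iter(self.signatures)

    def __len__(self) -> int:
        return len(self.signatures)

    def __getitem__(self, name: str) -> GeneSignature:
        for sig in self.signatures:
            if sig.name == name:
                return sig
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.signatures]

    def subset(self, names: Iterable[str]) -> "SignatureCollection":
        """Restrict to the given signature names, preserving their order."""
        wanted = list(names)
        return SignatureCollection(
            tuple(self[n] for n in wanted), source=self.source
        )

    def merge(self, other: "SignatureCollection", source: str = "") -> "SignatureCollection":
        return SignatureCollection(
            self.signatures + other.signatures,
            source=source or f"{self.source}+{other.source}",
        )

    def to_frame(self):
        """Long-format two-column table (signature, gene)."""
        import pandas as pd

        rows = [(s.name, g) for s in self.signatures for g in s.genes]
        return pd.DataFrame(rows, columns=["signature", "gene"])


def parse_gmt(path: str | Path, source: str = "") -> SignatureCollection:
    """Read a Broad-dialect GMT file (name, description, genes...).

    The description column is discarded and trailing empty fields are
    stripped.  Duplicate gene symbols within one line are collapsed to their
    first occurrence with a warning; lines with fewer than three fields raise
    :class:`GmtParseError` naming the offending line.
    """
    path = Path(path)
    signatures: list[GeneSignature] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            while fields and fields[-1] == "":
                fields.pop()
            if len(fields) < 3:
                raise GmtParseError(
                    f"{path.name}:{lineno}: expected >=3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            name, genes = fields[0], fields[2:]
            deduped = list(dict.fromkeys(genes))
            if len(deduped) != len(genes):
                warnings.warn(
                    f"{path.name}:{lineno}: signature {name!r} listed "
                    f"{len(genes) - len(deduped)} duplicate gene(s); collapsed",
                    stacklevel=2,
                )
            signatures.append(GeneSignature(name, tuple(deduped)))
    try:
        return SignatureCollection(tuple(signatures), source=source or str(path))
    except ValueError as exc:
        raise GmtParseError(f"{path.name}: {exc}") from exc


def write_gmt(collection: SignatureCollection, path: str | Path,
              description: str = "na") -> None:
    """Write a collection as a GMT file (inverse of :func:`parse_gmt`)."""
    with open(path, "w") as fh:
        for sig in collection:
            fh.write("\t".join([sig.name, description, *sig.genes]) + "\n")


@dataclass
class CollectionStats:
    """Gene bookkeeping for a signature collection.

    ``unique_genes`` counts genes that belong to exactly one signature;
    ``pairwise_overlap`` maps (name_a, name_b) to the size of the gene
    intersection, listing only nonzero overlaps.
    """

    n_signatures: int
    total_genes: int
    unique_genes: int
    membership: Mapping[str, int] = field(repr=False, default_factory=dict)
    pairwise_overlap: Mapping[tuple[str, str], int] = field(
        repr=False, default_factory=dict
    )


def collection_stats(collection: SignatureCollection) -> CollectionStats:
    """Totals over the gene union of a nonempty collection."""
    if len(collection) == 0:
        raise ValueError("collection is empty")
    membership: dict[str, int] = {}
    for sig in collection:
        for g in sig.genes:
            membership[g] = membership.get(g, 0) + 1
    overlaps: dict[tuple[str, str], int] = {}
    sigs = collection.signatures
    for i, a in enumerate(sigs):
        for b in sigs[i + 1:]:
            n = len(set(a.genes) & set(b.genes))
            if n:
                overlaps[(a.name, b.name)] = n
    return CollectionStats(
        n_signatures=len(collection),
        total_genes=len(membership),
        unique_genes=sum(1 for c in membership.values() if c == 1),
        membership=membership,
        pairwise_overlap=overlaps,
    )


APM_GENES = ("HLA-A", "HLA-B", "HLA-C", "B2M", "TAP1", "TAP2", "TAPBP")

CHECKPOINT_TARGETS = {"PD-1": "PDCD1", "PD-L1": "CD274", "CTLA-4": "CTLA4"}

BUILTIN_KEYS = ("bindea24", "apm", "angiogenesis", "checkpoint_targets")

_DATA_PACKAGE = "immunedecomp.data"


def _data_path(filename: str) -> Path:
    return Path(str(resources.files(_DATA_PACKAGE).joinpath(filename)))


def _verify_checksum(filename: str) -> None:
    manifest = json.loads(_data_path("MANIFEST.json").read_text())
    digest = hashlib.sha256(_data_path(filename).read_bytes()).hexdigest()
    if manifest.get(filename) != digest:
        raise RuntimeError(
            f"packaged data file {filename} does not match its pinned checksum"
        )


def builtin_signatures(key: str) -> SignatureCollection:
    """Return one of the packaged signature collections (see module docstring)."""
    if key == "apm":
        return SignatureCollection(
            (GeneSignature("APM", APM_GENES),), source="builtin:apm"
        )
    if key == "checkpoint_targets":
        return SignatureCollection(
            tuple(
                GeneSignature(name, (gene,))
                for name, gene in CHECKPOINT_TARGETS.items()
            ),
            source="builtin:checkpoint_targets",
        )
    if key in ("bindea24", "angiogenesis"):
        filename = f"{key}.gmt"
        _verify_checksum(filename)
        return parse_gmt(_data_path(filename), source=f"builtin:{key}")
    raise KeyError(
        f"unknown signature key {key!r}; valid keys: {', '.join(BUILTIN_KEYS)}"
    )
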