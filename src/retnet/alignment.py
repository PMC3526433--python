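"""Multi-gene DNA alignments and their site-pattern compression.

A :class:`GeneAlignmentSet` holds the per-gene alignments S_1..S_k of a
multi-locus data set.  All genes share one taxon set; the total number of
sites n = sum of gene lengths is the sample size used by BIC.  For likelihood
evaluation the site columns of *all* genes are pooled and deduplicated once,
so a single pruning pass over the unique patterns scores every gene.
"""
from __future__ import annotations

import csv
import uuid
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
from Bio import AlignIO, SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = ["Alignment", "GeneAlignmentSet", "read_manifest", "write_gene_set"]

_CODE = np.full(256, 4, dtype=np.uint8)  # 4 = missing / ambiguous
for _i, _c in enumerate("ACGT"):
    _CODE[ord(_c)] = _i
    _CODE[ord(_c.lower())] = _i


class Alignment:
    """One gene's alignment: taxon -> equal-length DNA sequence."""

    def __init__(self, sequences: Mapping[str, str], name: str = ""):
        if not sequences:
            raise ValueError("empty alignment")
        self.sequences = {t: str(s).upper() for t, s in sequences.items()}
        lens = {len(s) for s in self.sequences.values()}
        if len(lens) != 1:
            raise ValueError("sequences have unequal lengths")
        (self.n_sites,) = lens
        if self.n_sites < 1:
            raise ValueError("alignment has zero sites")
        self.name = name

    @property
    def taxa(self) -> tuple[str, ...]:
        return tuple(sorted(self.sequences))

    def encoded(self, taxa_order: Iterable[str]) -> np.ndarray:
        """(n_taxa, n_sites) uint8 matrix; A,C,G,T -> 0..3, anything else 4."""
        rows = [
            _CODE[np.frombuffer(self.sequences[t].encode(), dtype=np.uint8)]
            for t in taxa_order
        ]
        return np.vstack(rows)

    @classmethod
    def from_fasta(cls, path: str | Path, name: str = "") -> "Alignment":
        path = Path(path)
        recs = {r.id: str(r.seq) for r in SeqIO.parse(str(path), "fasta")}
        if not recs:
            raise ValueError(f"no FASTA records in {path}")
        return cls(recs, name=name or path.stem)

    @classmethod
    def from_phylip(cls, path: str | Path, name: str = "") -> "Alignment":
        path = Path(path)
        aln = AlignIO.read(str(path), "phylip-relaxed")
        return cls({r.id: str(r.seq) for r in aln}, name=name or path.stem)

    def to_fasta(self, path: str | Path) -> None:
        recs = [SeqRecord(Seq(s), id=t, description="") for t, s in sorted(self.sequences.items())]
        SeqIO.write(recs, str(path), "fasta")


class GeneAlignmentSet:
    """The ordered set S = {S_1, ..., S_k} of per-gene alignments."""

    def __init__(self, genes: Iterable[Alignment]):
        self.genes: list[Alignment] = list(genes)
        if not self.genes:
            raise ValueError("a gene set needs at least one gene")
        taxa = self.genes[0].taxa
        for g in self.genes:
            if g.taxa != taxa:
                raise ValueError("all genes must share the same taxon set")
        self.taxa: tuple[str, ...] = taxa
        self.n_sites: int = sum(g.n_sites for g in self.genes)
        self.token = uuid.uuid4().hex  # identity for likelihood caching
        self._patterns: tuple[np.ndarray, np.ndarray] | None = None

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)

    def patterns(self) -> tuple[np.ndarray, np.ndarray]:
        """Pooled unique site patterns across all genes.

        Returns ``(patterns, counts)`` with ``patterns`` of shape
        (n_taxa, U) and ``counts`` of shape (k, U): counts[g, j] is how many
        times pattern j occurs in gene g.
        """
        if self._patterns is None:
            mats = [g.encoded(self.taxa) for g in self.genes]
            allcols = np.concatenate(mats, axis=1)
            uniq, inverse = np.unique(allcols, axis=1, return_inverse=True)
            inverse = np.asarray(inverse).ravel()
            counts = np.zeros((len(self.genes), uniq.shape[1]))
            offset = 0
            for gi, g in enumerate(self.genes):
                idx = inverse[offset:offset + g.n_sites]
                counts[gi] = np.bincount(idx, minlength=uniq.shape[1])
                offset += g.n_sites
            self._patterns = (uniq, counts)
        return self._patterns


def read_manifest(path: str | Path) -> GeneAlignmentSet:
    """Load a gene set from a TSV manifest with columns gene_id, path, length.

    Paths are resolved relative to the manifest's directory; FASTA by default,
    relaxed PHYLIP for ``.phy``/``.phylip`` files.
    """
    path = Path(path)
    genes: list[Alignment] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            gene_path = Path(row["path"])
            if not gene_path.is_absolute():
                gene_path = path.parent / gene_path
            if not gene_path.exists():
                raise FileNotFoundError(f"gene file not found: {gene_path}")
            if gene_path.suffix in {".phy", ".phylip"}:
                aln = Alignment.from_phylip(gene_path, name=row["gene_id"])
            else:
                aln = Alignment.from_fasta(gene_path, name=row["gene_id"])
            if "length" in row and row["length"] and int(row["length"]) != aln.n_sites:
                raise ValueError(
                    f"gene {row['gene_id']}: manifest says {row['length']} sites, "
                    f"file has {aln.n_sites}"
                )
            genes.append(aln)
    return GeneAlignmentSet(genes)


def write_gene_set(genes: GeneAlignmentSet, outdir: str | Path) -> Path:
    """Write per-gene FASTA files plus a TSV manifest; returns manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = outdir / "manifest.tsv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["gene_id", "path", "length"])
        for i, g in enumerate(genes):
            gid = g.name or f"gene{i + 1}"
            fname = f"{gid}.fasta"
            g.to_fasta(outdir / fname)
            writer.writerow([gid, fname, g.n_sites])
    return manifest
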