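"""Reciprocal-best-hit orthologs, single-copy core families, and codon
back-translation of protein alignments."""

from __future__ import annotations

from io import StringIO
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd
from Bio.Seq import Seq

HIT_COLUMNS = ["query_gene", "subject_gene", "query_genome",
               "subject_genome", "bitscore", "evalue"]


def read_hit_table(path) -> pd.DataFrame:
    """Read a BLAST-outfmt-6-like hit table (TSV with a header)."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in HIT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"hit table missing columns {missing}")
    if (df["evalue"] < 0).any():
        raise ValueError("negative e-values in hit table")
    return df


def write_hit_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def best_hits(hits: pd.DataFrame, evalue_cutoff: float = 0.001
              ) -> dict[tuple[str, str], str]:
    """Best subject per (query gene, subject genome) under the cutoff.

    Ties break by higher bit score, then lexicographically smaller subject.
    """
    kept = hits[(hits["evalue"] <= evalue_cutoff)
                & (hits["query_genome"] != hits["subject_genome"])]
    kept = kept.sort_values(
        ["query_gene", "subject_genome", "bitscore", "subject_gene"],
        ascending=[True, True, False, True])
    first = kept.groupby(["query_gene", "subject_genome"], sort=False).head(1)
    return {
        (q, sg): s for q, sg, s in zip(
            first["query_gene"], first["subject_genome"],
            first["subject_gene"])
    }


def reciprocal_best_hits(
    hits: pd.DataFrame,
    evalue_cutoff: float = 0.001,
) -> frozenset[tuple[str, str]]:
    """Gene pairs that are each other's best cross-genome hits.

    Both directions must pass the e-value cutoff.  Pairs are returned as
    lexicographically ordered tuples.
    """
    best = best_hits(hits, evalue_cutoff)
    genome_of = {}
    for _, row in hits.iterrows():
        genome_of[row["query_gene"]] = row["query_genome"]
        genome_of[row["subject_gene"]] = row["subject_genome"]
    pairs = set()
    for (q, sg), s in best.items():
        qg = genome_of[q]
        if best.get((s, qg)) == q:
            pairs.add(tuple(sorted((q, s))))
    return frozenset(pairs)


def single_copy_core(
    bbh_pairs: Iterable[tuple[str, str]],
    gene_to_genome: Mapping[str, str],
    genomes: Iterable[str],
) -> list[frozenset[str]]:
    """Ortholog groups spanning every genome exactly once.

    Groups are connected components of the BBH graph; components that miss
    a genome or contain more than one gene from any genome are discarded.
    Returned sorted by their smallest member for determinism.
    """
    genomes = frozenset(genomes)
    graph = nx.Graph()
    graph.add_edges_from(bbh_pairs)
    groups = []
    for comp in nx.connected_components(graph):
        by_genome: dict[str, int] = {}
        for gene in comp:
            by_genome[gene_to_genome[gene]] = \
                by_genome.get(gene_to_genome[gene], 0) + 1
        if set(by_genome) == genomes and all(v == 1 for v in by_genome.values()):
            groups.append(frozenset(comp))
    return sorted(groups, key=lambda g: min(g))


class BacktranslationError(ValueError):
    pass


def backtranslate_alignment(
    protein_alignment: Mapping[str, str],
    cds: Mapping[str, str],
) -> dict[str, str]:
    """Place each CDS's codons under its aligned protein residues.

    Protein gaps become ``---`` triplets.  Each CDS (with any trailing stop
    codon removed) must translate exactly to its ungapped protein row; a
    mismatch raises an error naming the taxon and residue position.
    """
    out = {}
    lengths = {len(s) for s in protein_alignment.values()}
    if len(lengths) > 1:
        raise BacktranslationError("protein alignment rows differ in length")
    for taxon, prot in protein_alignment.items():
        if taxon not in cds:
            raise BacktranslationError(f"no CDS for taxon {taxon!r}")
        dna = cds[taxon].upper().replace("U", "T")
        if len(dna) % 3:
            raise BacktranslationError(
                f"taxon {taxon!r}: CDS length {len(dna)} not divisible by 3")
        codons = [dna[i:i + 3] for i in range(0, len(dna), 3)]
        if codons and str(Seq(codons[-1]).translate()) == "*":
            codons = codons[:-1]
        ungapped = prot.replace("-", "")
        if len(codons) != len(ungapped):
            raise BacktranslationError(
                f"taxon {taxon!r}: {len(codons)} codons vs "
                f"{len(ungapped)} residues")
        row = []
        k = 0
        for pos, aa in enumerate(prot, start=1):
            if aa == "-":
                row.append("---")
                continue
            codon = codons[k]
            translated = str(Seq(codon).translate())
            if translated != aa.upper():
                raise BacktranslationError(
                    f"taxon {taxon!r}, residue {pos}: codon {codon} "
                    f"translates to {translated!r}, protein has {aa!r}")
            row.append(codon)
            k += 1
        out[taxon] = "".join(row)
    return out


def read_fasta(path) -> dict[str, str]:
    from Bio import SeqIO
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path) -> None:
    with open(path, "w") as fh:
        for name in sequences:
            fh.write(f">{name}\n{sequences[name]}\n")
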