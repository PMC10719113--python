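"""Readers/writers for the plain-text interchange formats used at the
package boundaries: ALLC-style basecall tables, BED intervals, contact
triplets, MEME-like PWM files and FASTA (via Biopython)."""

from __future__ import annotations

import os

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from scipy import sparse
from scipy.io import mmwrite

ALLC_COLUMNS = ["chrom", "pos", "strand", "context", "mc", "cov", "methylated"]


def write_allc(path, chrom, positions, contexts, mc, cov) -> None:
    """Write one cell's basecalls as an ALLC-style TSV.

    Columns: chrom, pos (1-based, as in the ALLC lineage), strand, context,
    mc, cov, methylated flag.  Bins with zero coverage are omitted.
    """
    keep = cov > 0
    df = pd.DataFrame({
        "chrom": chrom,
        "pos": np.asarray(positions)[keep] + 1,
        "strand": "+",
        "context": np.asarray(contexts)[keep],
        "mc": np.asarray(mc)[keep],
        "cov": np.asarray(cov)[keep],
        "methylated": 1,
    })
    df.to_csv(path, sep="\t", header=False, index=False)


def read_allc(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, names=ALLC_COLUMNS)
    df["pos"] -= 1  # back to 0-based
    return df


def write_bed(path, intervals, names=None, scores=None) -> None:
    """Write (chrom, start, end) 0-based half-open intervals as BED."""
    rows = []
    for i, (chrom, start, end) in enumerate(intervals):
        row = [chrom, int(start), int(end)]
        if names is not None:
            row.append(names[i])
        if scores is not None:
            row.append(scores[i])
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


def read_bed(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.rename(columns={0: "chrom", 1: "start", 2: "end"})
    return df


def write_contacts_triplet(path, matrix: sparse.spmatrix, resolution: int,
                           chrom: str) -> None:
    """Upper-triangle triplet TSV: chrom, bin1_start, bin2_start, count."""
    coo = sparse.triu(matrix.tocoo())
    df = pd.DataFrame({
        "chrom": chrom,
        "start1": coo.row * resolution,
        "start2": coo.col * resolution,
        "count": coo.data,
    })
    df.to_csv(path, sep="\t", header=False, index=False)


def read_contacts_triplet(path, resolution: int, n_bins: int) -> sparse.csr_matrix:
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start1", "start2", "count"])
    i = (df["start1"] // resolution).to_numpy()
    j = (df["start2"] // resolution).to_numpy()
    m = sparse.coo_matrix((df["count"], (i, j)), shape=(n_bins, n_bins))
    return m.tocsr()


def write_counts_mtx(path, matrix) -> None:
    mmwrite(path, sparse.csr_matrix(matrix))


def write_fasta(path, sequences: dict) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="")
               for name, seq in sequences.items()]
    SeqIO.write(records, path, "fasta")


def read_fasta(path) -> dict:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(path, "fasta")}


def write_meme(path, pwms: dict, background=None) -> None:
    """Write PWMs in MEME minimal motif format (ACGT alphabet)."""
    bg = background if background is not None else [0.25] * 4
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\n")
        fh.write("Background letter frequencies\n")
        fh.write("A %.5f C %.5f G %.5f T %.5f\n\n" % tuple(bg))
        for name, pwm in pwms.items():
            pwm = np.asarray(pwm, dtype=float)
            fh.write(f"MOTIF {name}\n")
            fh.write(f"letter-probability matrix: alength= 4 w= {pwm.shape[0]}\n")
            for row in pwm:
                fh.write(" ".join(f"{x:.6f}" for x in row) + "\n")
            fh.write("\n")


def read_meme(path) -> dict:
    """Parse a MEME minimal motif file into {name: (w, 4) array}."""
    pwms, name, rows = {}, None, []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("MOTIF"):
                if name is not None and rows:
                    pwms[name] = np.array(rows)
                name, rows = line.split()[1], []
            elif name is not None and line:
                parts = line.split()
                if len(parts) == 4:
                    try:
                        rows.append([float(x) for x in parts])
                    except ValueError:
                        pass
    if name is not None and rows:
        pwms[name] = np.array(rows)
    return pwms


def write_gtf(path, genes) -> None:
    """Write a minimal GTF from gene dicts with keys: chrom, gene_id, strand,
    transcripts = {tx_id: [(exon_start, exon_end), ...]} (0-based half-open;
    written 1-based closed per GTF convention)."""
    with open(path, "w") as fh:
        for g in genes:
            starts = [s for tx in g["transcripts"].values() for s, _ in tx]
            ends = [e for tx in g["transcripts"].values() for _, e in tx]
            attrs = f'gene_id "{g["gene_id"]}";'
            fh.write("\t".join(map(str, [g["chrom"], "sim", "gene",
                                         min(starts) + 1, max(ends), ".",
                                         g["strand"], ".", attrs])) + "\n")
            for tx_id, exons in g["transcripts"].items():
                tattrs = f'gene_id "{g["gene_id"]}"; transcript_id "{tx_id}";'
                fh.write("\t".join(map(str, [g["chrom"], "sim", "transcript",
                                             exons[0][0] + 1, exons[-1][1], ".",
                                             g["strand"], ".", tattrs])) + "\n")
                for s, e in exons:
                    fh.write("\t".join(map(str, [g["chrom"], "sim", "exon",
                                                 s + 1, e, ".", g["strand"],
                                                 ".", tattrs])) + "\n")


def ensure_dir(path) -> str:
    os.makedirs(path, exist_ok=True)
    return path
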