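"""Reading and writing the pipeline's file formats.

Sequence I/O goes through Biopython; tables are plain TSV via pandas with a
fixed float format so that repeated runs are byte-identical.  A simulated
dataset is materialised as a codon alignment FASTA (gaps as ``---``), a
newick tree, a ground-truth JSON and the generating config in YAML.
"""

from __future__ import annotations

import dataclasses
import json
import os

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .seg import LcrInterval, ProteinRecord
from .simulate import GeneFamily, Gradient, SimConfig, SimulatedDataset, TruthRecord

FLOAT_FORMAT = "%.10g"


def read_proteins(path) -> list:
    """Protein FASTA -> list of ProteinRecord."""
    return [ProteinRecord(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(path, "fasta")]


def write_fasta(records: dict, path) -> None:
    """Write ``{id: sequence}`` as FASTA (insertion order preserved)."""
    seqs = [SeqRecord(Seq(s), id=name, description="") for name, s in records.items()]
    SeqIO.write(seqs, path, "fasta")


def write_lcr_tsv(lcrs: list, path) -> None:
    df = pd.DataFrame(
        [(l.protein_id, l.start, l.end, l.entropy_min) for l in lcrs],
        columns=["protein_id", "start", "end", "min_entropy"],
    )
    write_table(df, path)


def read_lcr_tsv(path) -> list:
    df = pd.read_csv(path, sep="\t")
    return [
        LcrInterval(r.protein_id, int(r.start), int(r.end), float(r.min_entropy))
        for r in df.itertuples()
    ]


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Simulated datasets
# ---------------------------------------------------------------------------

def write_dataset(dataset: SimulatedDataset, out_dir) -> None:
    os.makedirs(out_dir, exist_ok=True)
    codon_rows = {}
    cds_rows = {}
    protein_rows = {}
    truth = {}
    for gene in dataset.genes:
        for sp, codons in sorted(gene.codon_alignment.items()):
            name = f"{gene.gene_id}|{sp}"
            codon_rows[name] = "".join("---" if c is None else c for c in codons)
            cds_rows[name] = gene.cds(sp)
            protein_rows[name] = gene.protein(sp).residues
        truth[gene.gene_id] = {
            "lcr_start": gene.truth.lcr_start,
            "lcr_end": gene.truth.lcr_end,
            "events": gene.truth.events,
            "deletions": [list(d) for d in gene.truth.deletions],
        }
    write_fasta(codon_rows, os.path.join(out_dir, "codon_alignment.fa"))
    write_fasta(cds_rows, os.path.join(out_dir, "cds.fa"))
    write_fasta(protein_rows, os.path.join(out_dir, "proteins.fa"))
    with open(os.path.join(out_dir, "tree.nwk"), "w") as fh:
        fh.write(dataset.config.newick + "\n")
    with open(os.path.join(out_dir, "truth.json"), "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
    with open(os.path.join(out_dir, "config.yaml"), "w") as fh:
        yaml.safe_dump(config_to_dict(dataset.config), fh, sort_keys=True)


def config_to_dict(config: SimConfig) -> dict:
    d = dataclasses.asdict(config)
    return d


def config_from_dict(d: dict) -> SimConfig:
    kwargs = dict(d)
    for key, val in kwargs.items():
        if isinstance(val, dict) and set(val) == {"amplitude", "scale"}:
            kwargs[key] = Gradient(**val)
    return SimConfig(**kwargs)


def read_config(path) -> SimConfig:
    with open(path) as fh:
        return config_from_dict(yaml.safe_load(fh))


def read_dataset(in_dir) -> SimulatedDataset:
    config = read_config(os.path.join(in_dir, "config.yaml"))
    with open(os.path.join(in_dir, "truth.json")) as fh:
        truth = json.load(fh)
    rows: dict = {}
    for rec in SeqIO.parse(os.path.join(in_dir, "codon_alignment.fa"), "fasta"):
        gene_id, sp = rec.id.split("|")
        seq = str(rec.seq)
        codons = [
            None if seq[i : i + 3] == "---" else seq[i : i + 3]
            for i in range(0, len(seq), 3)
        ]
        rows.setdefault(gene_id, {})[sp] = codons
    genes = []
    for gene_id in sorted(rows):
        t = truth[gene_id]
        tr = TruthRecord(
            gene_id, t["lcr_start"], t["lcr_end"], t["events"],
            [tuple(d) for d in t["deletions"]],
        )
        genes.append(GeneFamily(gene_id, rows[gene_id], tr))
    return SimulatedDataset(config, genes)
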