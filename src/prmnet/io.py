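"""Readers and writers for the package's on-disk formats.

Plain-text formats only: FASTA (Biopython), newick, and TSV tables.
Internally all coordinates are 0-based half-open; exported tables use
1-based inclusive coordinates and say so in a header comment.
"""

from __future__ import annotations

import os
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from prmnet.network import SpeciesNetwork
from prmnet.pwm import AMINO_ACIDS, PWM, ScoredSite, build_pwm

COORD_COMMENT = "# coordinates: 1-based, inclusive start/end\n"


def write_fasta(path: str, sequences: Mapping[str, str]) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    SeqIO.write(records, path, "fasta")


def read_fasta(path: str) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(path, "fasta")}


def write_pwm(path: str, pwm: PWM, kind: str = "counts") -> None:
    """PWM as TSV: rows = positions, columns = the 20 amino acids."""
    if kind not in ("counts", "adjusted"):
        raise ValueError("kind must be 'counts' or 'adjusted'")
    matrix = pwm.raw_counts if kind == "counts" else pwm.adjusted
    with open(path, "w") as fh:
        fh.write(f"#class_id={pwm.class_id}\n#type={kind}\n")
        fh.write("position\t" + "\t".join(AMINO_ACIDS) + "\n")
        for p, row in enumerate(matrix):
            fh.write(str(p) + "\t" + "\t".join(f"{v:.10g}" for v in row) + "\n")


def read_pwm(path: str) -> PWM:
    class_id, kind = "pwm", "counts"
    with open(path) as fh:
        lines = fh.read().splitlines()
    body = []
    for line in lines:
        if line.startswith("#class_id="):
            class_id = line.split("=", 1)[1]
        elif line.startswith("#type="):
            kind = line.split("=", 1)[1]
        elif line and not line.startswith("#"):
            body.append(line.split("\t"))
    matrix = np.array([[float(v) for v in row[1:]] for row in body[1:]])
    if kind == "adjusted":
        return PWM.from_adjusted(class_id, matrix)
    return build_pwm(matrix, class_id)


def read_pwm_dir(directory: str) -> dict[str, PWM]:
    out = {}
    for name in sorted(os.listdir(directory)):
        if name.endswith(".tsv"):
            pwm = read_pwm(os.path.join(directory, name))
            out[pwm.class_id] = pwm
    return out


def write_tracks(path: str, tracks: Mapping[str, tuple[Sequence[float], Sequence[float]]]) -> None:
    """Per-residue tracks: protein_id, position (1-based), disorder,
    accessibility."""
    with open(path, "w") as fh:
        fh.write("# coordinates: positions are 1-based\n")
        fh.write("protein_id\tposition\tdisorder\taccessibility\n")
        for protein in tracks:
            dis, acc = tracks[protein]
            for i, (d, a) in enumerate(zip(dis, acc)):
                fh.write(f"{protein}\t{i + 1}\t{d:.6g}\t{a:.6g}\n")


def read_tracks(path: str) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    df = pd.read_csv(path, sep="\t", comment="#")
    out = {}
    for protein, sub in df.groupby("protein_id", sort=False):
        sub = sub.sort_values("position")
        out[str(protein)] = (
            sub["disorder"].to_numpy(float),
            sub["accessibility"].to_numpy(float),
        )
    return out


SITE_COLUMNS = [
    "species", "target_protein", "class_id", "start", "end",
    "peptide", "score", "accessibility", "disorder",
]


def write_sites(path: str, sites: Iterable[ScoredSite]) -> None:
    with open(path, "w") as fh:
        fh.write(COORD_COMMENT)
        fh.write("\t".join(SITE_COLUMNS) + "\n")
        for s in sites:
            fh.write(
                f"{s.species}\t{s.target_protein}\t{s.class_id}\t{s.start + 1}\t{s.end}"
                f"\t{s.peptide}\t{s.score:.8g}\t{s.accessibility:.8g}\t{s.disorder:.8g}\n"
            )


def read_sites(path: str) -> list[ScoredSite]:
    df = pd.read_csv(path, sep="\t", comment="#")
    return [
        ScoredSite(
            str(r.species), str(r.target_protein), str(r.class_id),
            int(r.start) - 1, int(r.end), str(r.peptide),
            float(r.score), float(r.accessibility), float(r.disorder),
        )
        for r in df.itertuples()
    ]


def write_network(path: str, net: SpeciesNetwork) -> None:
    """Edge list with one row per accepted site."""
    with open(path, "w") as fh:
        fh.write(COORD_COMMENT)
        fh.write(
            "species\tdomain_protein\tclass_id\ttarget_protein\tstart\tend"
            "\tscore\taccessibility\tdisorder\n"
        )
        for edge in sorted(net.edges):
            d, c, t = edge
            for s in net.sites.get(edge, []):
                fh.write(
                    f"{net.species}\t{d}\t{c}\t{t}\t{s.start + 1}\t{s.end}"
                    f"\t{s.score:.8g}\t{s.accessibility:.8g}\t{s.disorder:.8g}\n"
                )


def read_network(path: str, domain_proteins: Iterable[str] = ()) -> SpeciesNetwork:
    df = pd.read_csv(path, sep="\t", comment="#")
    species = str(df["species"].iloc[0]) if len(df) else ""
    net = SpeciesNetwork(species=species, domain_proteins=set(domain_proteins))
    for r in df.itertuples():
        edge = (str(r.domain_protein), str(r.class_id), str(r.target_protein))
        net.edges.add(edge)
        site = ScoredSite(
            species, str(r.target_protein), str(r.class_id),
            int(r.start) - 1, int(r.end), "",
            float(r.score), float(r.accessibility), float(r.disorder),
        )
        net.sites.setdefault(edge, []).append(site)
        net.domain_proteins.add(str(r.domain_protein))
    return net


def write_orthology(path: str, rows: Iterable[tuple[str, str, str]]) -> None:
    with open(path, "w") as fh:
        fh.write("orthogroup_id\tspecies\tprotein_id\n")
        for og, sp, p in rows:
            fh.write(f"{og}\t{sp}\t{p}\n")


def read_orthology(path: str) -> list[tuple[str, str, str]]:
    df = pd.read_csv(path, sep="\t", comment="#")
    return [
        (str(r.orthogroup_id), str(r.species), str(r.protein_id)) for r in df.itertuples()
    ]
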