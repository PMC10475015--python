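"""FASTA / BED / GFF3 / TSV input-output and run manifests.

Internal coordinates are 0-based half-open everywhere; BED is native,
GFF3 (1-based inclusive) is produced by exact conversion.  FASTA input
(plain or gzipped) is normalized to uppercase {A,C,G,T,N}: IUPAC
ambiguity codes other than N map to N with a warning.
"""

from __future__ import annotations

import gzip
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO

_VALID = set("ACGTN")


def _open_maybe_gzip(path):
    path = Path(path)
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_fasta(path) -> dict[str, str]:
    """Read (optionally gzipped) FASTA into {id: normalized sequence}.

    Ids are the first whitespace-delimited token of the header.
    """
    records: dict[str, str] = {}
    with _open_maybe_gzip(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            seq = str(rec.seq).upper()
            if not set(seq) <= _VALID:
                bad = sorted(set(seq) - _VALID)
                warnings.warn(
                    f"record {rec.id}: ambiguity codes {bad} mapped to N"
                )
                seq = "".join(c if c in _VALID else "N" for c in seq)
            records[rec.id] = seq
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: dict[str, str], path, width: int = 80):
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


@dataclass
class Interval:
    chrom: str
    start: int
    end: int
    name: str = "."
    score: int = 0
    strand: str = "."


def export_bed(entities: list, path):
    """BED6: 0-based half-open, strand in column 6.  Input must be sorted."""
    _check_sorted(entities)
    with open(path, "w") as fh:
        for e in entities:
            name = getattr(e, "family", getattr(e, "name", "."))
            score = getattr(e, "edits", getattr(e, "score", 0))
            strand = getattr(e, "strand", ".")
            fh.write(f"{e.chrom}\t{e.start}\t{e.end}\t{name}\t{score}\t{strand}\n")


def export_gff(entities: list, path, source: str = "horscope", feature: str = "repeat_unit"):
    """GFF3: 1-based inclusive coordinates (start+1, end)."""
    _check_sorted(entities)
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for e in entities:
            name = getattr(e, "family", getattr(e, "name", "."))
            strand = getattr(e, "strand", ".")
            fh.write(
                f"{e.chrom}\t{source}\t{feature}\t{e.start + 1}\t{e.end}\t.\t"
                f"{strand}\t.\tName={name}\n"
            )


def read_bed(path) -> list[Interval]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            out.append(
                Interval(
                    chrom=f[0],
                    start=int(f[1]),
                    end=int(f[2]),
                    name=f[3] if len(f) > 3 else ".",
                    score=int(f[4]) if len(f) > 4 else 0,
                    strand=f[5] if len(f) > 5 else ".",
                )
            )
    return out


def read_gff(path) -> list[Interval]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            name = "."
            for kv in f[8].split(";"):
                if kv.startswith("Name="):
                    name = kv[5:]
            out.append(
                Interval(
                    chrom=f[0],
                    start=int(f[3]) - 1,
                    end=int(f[4]),
                    name=name,
                    strand=f[6],
                )
            )
    return out


def _check_sorted(entities):
    for a, b in zip(entities, entities[1:]):
        if (a.chrom, a.start) > (b.chrom, b.start):
            raise ValueError("entities must be sorted by (chrom, start)")


def hits_to_dataframe(hits) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": h.chrom,
                "start": h.start,
                "end": h.end,
                "family": h.family,
                "strand": h.strand,
                "edits": h.edits,
                "divergence": h.divergence,
            }
            for h in hits
        ],
        columns=["chrom", "start", "end", "family", "strand", "edits", "divergence"],
    )


def hits_from_dataframe(df: pd.DataFrame):
    from horscope.scan import MonomerHit

    return [
        MonomerHit(
            chrom=r.chrom,
            start=int(r.start),
            end=int(r.end),
            family=r.family,
            strand=r.strand,
            edits=int(r.edits),
            divergence=float(r.divergence),
        )
        for r in df.itertuples()
    ]


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    version: str = "0.1.0"
    config: dict = field(default_factory=dict)
    inputs: dict = field(default_factory=dict)  # path -> sha256
    outputs: dict = field(default_factory=dict)  # stage -> {path: sha256}
    stats: dict = field(default_factory=dict)

    def save(self, path):
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=1, sort_keys=True)

    @classmethod
    def load(cls, path):
        with open(path) as fh:
            return cls(**json.load(fh))
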