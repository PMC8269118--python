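"""FASTA input, result serialization and run configuration."""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

from Bio import SeqIO

from .cyclic_align import render_alignment
from .pwm import matrix_to_json

logger = logging.getLogger("divrep")

ANNOTATION_COLUMNS = ("id", "n0", "l", "r", "Z", "S", "F_max")


@dataclass
class RunConfig:
    """All tunables of a scan, with the method's published defaults."""

    n_min: int = 2
    n_max: int | None = None   # capped at min(100, len(seq) // 2)
    set_size: int = 1000
    shuffles: int = 200
    z0: float = 6.0
    del_penalty: float = 25.0
    seed: int = 0
    threads: int = 1           # accepted for CLI compatibility; results are
                               # schedule-independent and computed sequentially
    symbol_space: str = "residues20"
    min_span: int = 14


def read_fasta(path) -> list[tuple[str, str]]:
    """Read (id, upper-cased sequence) pairs; descriptions are retained in id."""
    path = Path(path)
    records = []
    try:
        for rec in SeqIO.parse(str(path), "fasta"):
            records.append((rec.description, str(rec.seq).upper()))
    except ValueError as exc:
        raise ValueError(f"malformed FASTA in {path}: {exc}") from exc
    return records


def write_annotations(annotations, prefix) -> list[Path]:
    """Write a TSV summary plus one JSON per hit (matrix + alignment)."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    tsv = prefix.with_suffix(".tsv")
    written = [tsv]
    with open(tsv, "w") as fh:
        fh.write("\t".join(ANNOTATION_COLUMNS) + "\n")
        for ann in annotations:
            s = "" if ann.s is None else f"{ann.s:.4f}"
            fh.write(
                f"{ann.sequence_id}\t{ann.n0}\t{ann.l}\t{ann.r}\t"
                f"{ann.z:.3f}\t{s}\t{ann.f_max:.3f}\n"
            )
    for idx, ann in enumerate(annotations):
        hit = prefix.parent / f"{prefix.name}_hit{idx}.json"
        payload = {
            "id": ann.sequence_id,
            "n0": ann.n0,
            "l": ann.l,
            "r": ann.r,
            "Z": ann.z,
            "S": ann.s,
            "F_max": ann.f_max,
            "M_max": json.loads(matrix_to_json(ann.m_max)),
            "alignment": render_alignment(ann.alignment),
        }
        hit.write_text(json.dumps(payload, indent=1))
        written.append(hit)
    return written


def write_truth(labeled, path) -> Path:
    """Ground-truth TSV for simulated sequences."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("id\tl0\tr0\tn\ti\tk\tseed\n")
        for ls in labeled:
            fh.write(
                f"{ls.id}\t{ls.l0}\t{ls.r0}\t{ls.n}\t"
                f"{ls.spec.substitution_percent:g}\t{ls.spec.k}\t{ls.spec.seed}\n"
            )
    return path
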