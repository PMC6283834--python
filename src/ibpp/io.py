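"""FASTA, image, truth-table and hit-table input/output."""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .image import Image
from .scanner import Hit
from .scoring import ScoreConfig


def read_fasta(path: Path | str) -> list[tuple[str, str]]:
    """Parse a FASTA file into ``(id, lowercase sequence)`` pairs.

    Record order is preserved; duplicate ids are rejected.  A non-empty
    file that yields no records is reported as malformed with the line
    number of the first offending line.
    """
    path = Path(path)
    records = []
    seen = set()
    try:
        for rec in SeqIO.parse(str(path), "fasta"):
            if rec.id in seen:
                raise ValueError(f"{path}: duplicate FASTA id {rec.id!r}")
            seen.add(rec.id)
            records.append((rec.id, str(rec.seq).lower()))
    except ValueError as err:
        if "duplicate" in str(err):
            raise
        records = []
    if not records:
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                if line.strip():
                    raise ValueError(
                        f"{path}:{lineno}: malformed FASTA (expected '>' header, "
                        f"got {line.strip()[:20]!r})"
                    )
    return records


def write_fasta(records: list[tuple[str, str]], path: Path | str) -> None:
    seq_records = [
        SeqRecord(Seq(seq), id=rid, description="") for rid, seq in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")


# -- images -----------------------------------------------------------------


def save_image_text(image: Image, path: Path | str) -> None:
    """One-line plain-text serialization of an image."""
    Path(path).write_text(image.chars + "\n")


def load_image_text(path: Path | str) -> Image:
    return Image(Path(path).read_text().strip())


def save_image_json(
    image: Image,
    path: Path | str,
    *,
    d_score: float | None = None,
    generation: int | None = None,
    score_config: ScoreConfig | None = None,
) -> None:
    """Image plus training metadata as JSON."""
    payload = {
        "chars": image.chars,
        "width": image.width,
        "d_score": d_score,
        "generation": generation,
        "score_config": asdict(score_config) if score_config else None,
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def load_image_json(path: Path | str) -> tuple[Image, dict]:
    payload = json.loads(Path(path).read_text())
    meta = {k: v for k, v in payload.items() if k not in ("chars",)}
    return Image(payload["chars"]), meta


# -- truth tables and hits --------------------------------------------------


def write_truth_tsv(path: Path | str, rows: list[tuple[str, int, int]]) -> None:
    """Truth table for long-sequence evaluation: id, TSS, sequence length."""
    df = pd.DataFrame(rows, columns=["sequence_id", "tss_position", "length"])
    df.to_csv(path, sep="\t", index=False)


def read_truth_tsv(path: Path | str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_hits_tsv(hits: list[Hit], path: Path | str, mode: str = "ibpp") -> None:
    df = pd.DataFrame(
        [
            {
                "sequence_id": h.sequence_id,
                "window_start": h.window_start,
                "tss_position": h.tss_position,
                "score": h.score,
                "strand": h.strand,
                "mode": mode,
            }
            for h in hits
        ],
        columns=["sequence_id", "window_start", "tss_position", "score", "strand", "mode"],
    )
    df.to_csv(path, sep="\t", index=False)


def read_hits_tsv(path: Path | str) -> list[Hit]:
    df = pd.read_csv(path, sep="\t")
    return [
        Hit(
            sequence_id=str(r.sequence_id),
            window_start=int(r.window_start),
            tss_position=int(r.tss_position),
            score=float(r.score),
            strand=str(r.strand),
        )
        for r in df.itertuples()
    ]


def write_hits_bed(hits: list[Hit], path: Path | str) -> None:
    """BED6 (0-based half-open): one interval per predicted TSS."""
    with open(path, "w") as fh:
        for i, h in enumerate(hits):
            fh.write(
                f"{h.sequence_id}\t{h.tss_position}\t{h.tss_position + 1}\t"
                f"window_{h.window_start}\t{h.score:.4f}\t{h.strand}\n"
            )
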