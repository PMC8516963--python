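"""File formats: FASTA, aligned FASTA, Newick, TSV tables, JSON reports.

All written coordinates are 1-based inclusive with an explicit strand
column; in-memory coordinates are 0-based half-open.  Writes are atomic
(temp file in the target directory, then rename).
"""

from __future__ import annotations

import json
import os
import tempfile
from contextlib import contextmanager
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple, Union

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .pssm import ProfileMatrix
from .screen import PresenceCall

PathLike = Union[str, Path]


@contextmanager
def atomic_write(path: PathLike, mode: str = "w"):
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, mode) as fh:
            yield fh
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


# -- FASTA ------------------------------------------------------------------

def read_fasta(path: PathLike) -> Dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: Mapping[str, str], path: PathLike) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    with atomic_write(path) as fh:
        SeqIO.write(records, fh, "fasta")


def read_alignment(path: PathLike) -> List[Tuple[str, str]]:
    rows = [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]
    if not rows:
        raise ValueError(f"empty alignment: {path}")
    width = len(rows[0][1])
    if any(len(r[1]) != width for r in rows):
        raise ValueError(f"ragged alignment: {path}")
    return rows


# -- TSV tables -------------------------------------------------------------

def write_tsv(df: pd.DataFrame, path: PathLike, index: bool = False) -> None:
    with atomic_write(path) as fh:
        df.to_csv(fh, sep="\t", index=index)


def read_tsv(path: PathLike, **kw) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kw)


def calls_to_frame(calls: Sequence[PresenceCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        best = c.best
        rows.append(
            {
                "family": c.family_id,
                "taxon": c.taxon,
                "state": c.state,
                "tier": c.tier,
                "best_target": best.target_id if best else "",
                "start": best.start + 1 if best else 0,  # 1-based inclusive
                "end": best.end if best else 0,
                "strand": "+" if best else "",
                "bitscore": round(best.bitscore, 3) if best else 0.0,
                "evalue": best.evalue if best else "",
                "paralogs": c.paralogs,
                "flags": ";".join(c.flags),
            }
        )
    return pd.DataFrame(rows)


def frame_to_calls(df: pd.DataFrame) -> List[PresenceCall]:
    calls = []
    for _, row in df.iterrows():
        calls.append(
            PresenceCall(
                str(row["family"]), str(row["taxon"]), str(row["state"]),
                str(row["tier"]), best=None,
                paralogs=int(row.get("paralogs", 0) or 0),
                flags=[f for f in str(row.get("flags", "") or "").split(";") if f],
            )
        )
    return calls


def write_profile(profile: ProfileMatrix, path: PathLike) -> None:
    write_tsv(profile.to_frame(), path)


def write_json(obj, path: PathLike) -> None:
    with atomic_write(path) as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def write_kmer_table(counts: Mapping[str, int], path: PathLike) -> None:
    df = pd.DataFrame(sorted(counts.items()), columns=["kmer", "count"])
    write_tsv(df, path)


def read_kmer_table(path: PathLike) -> Dict[str, int]:
    df = read_tsv(path)
    return dict(zip(df["kmer"], df["count"].astype(int)))


def read_complexes(path: PathLike) -> pd.DataFrame:
    """Complex definition TSV with columns ``complex, member`` (one row per
    member) and an optional ``color`` column."""
    df = read_tsv(path)
    required = {"complex", "member"}
    if not required.issubset(df.columns):
        raise ValueError(f"complex table needs columns {sorted(required)}")
    return df
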