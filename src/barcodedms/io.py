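"""File formats: FASTA/FASTQ readers, TSV schemas, codebook and design
serialization, YAML run configuration.

TSV (tab-separated, header row, UTF-8, '.' decimal) is the canonical
tabular dialect; CSV is accepted on read. FASTQ qualities are parsed but
unused downstream.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .design import (
    BSAI_MODULE,
    BarcodeCodebook,
    CodingSequence,
    OPoolDesign,
)
from .readproc import FragmentReference, MergedRead

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_cds",
    "read_reads",
    "read_tsv",
    "write_tsv",
    "read_yaml_config",
    "write_run_config",
    "write_codebook",
    "read_codebook",
    "design_to_frame",
    "write_design",
    "read_design_frame",
    "fragment_reference_from_frame",
    "write_opool_sheet",
]


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """(id, sequence) pairs from a FASTA file."""
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    SeqIO.write(
        (SeqRecord(Seq(seq), id=name, description="") for name, seq in records),
        str(path),
        "fasta",
    )


def read_cds(path: str | Path, *, allow_internal_stops: bool = False
             ) -> CodingSequence:
    """First record of a FASTA file as a validated coding sequence."""
    records = read_fasta(path)
    if not records:
        raise ValueError(f"{path}: no FASTA records")
    name, seq = records[0]
    return CodingSequence(id=name, seq=seq, allow_internal_stops=allow_internal_stops)


def read_reads(path: str | Path) -> list[MergedRead]:
    """Merged reads from FASTQ or FASTA (by extension; qualities ignored)."""
    path = Path(path)
    fmt = "fastq" if path.suffix.lower() in (".fastq", ".fq") else "fasta"
    try:
        return [
            MergedRead(id=rec.id, seq=str(rec.seq).upper())
            for rec in SeqIO.parse(str(path), fmt)
        ]
    except ValueError as exc:
        raise ValueError(f"{path}: malformed {fmt.upper()} ({exc})") from exc


def read_tsv(path: str | Path, required_columns: Sequence[str] | None = None
             ) -> pd.DataFrame:
    """Read TSV (or CSV) and validate the declared schema."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep)
    if required_columns:
        missing = [c for c in required_columns if c not in df.columns]
        if missing:
            raise ValueError(f"{path}: missing required columns {missing}")
    return df


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_yaml_config(path: str | Path) -> dict:
    with open(path) as fh:
        config = yaml.safe_load(fh)
    if not isinstance(config, dict):
        raise ValueError(f"{path}: config must be a YAML mapping")
    return config


def write_run_config(params: dict, out_dir: str | Path,
                     name: str = "run_config.yaml") -> None:
    """Serialize the exact parameters of a run next to its outputs."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    payload = {"tool": "barcodedms", "version": __version__, **params}
    with open(out_dir / name, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Codebook
# ---------------------------------------------------------------------------


def write_codebook(codebook: BarcodeCodebook, path: str | Path) -> None:
    """One barcode per line, plus a JSON sidecar of constraint parameters."""
    path = Path(path)
    path.write_text("\n".join(codebook.members) + "\n")
    sidecar = {
        "k": codebook.k,
        "min_hamming": codebook.min_hamming,
        "gc_min": codebook.gc_min,
        "gc_max": codebook.gc_max,
        "forbidden_motifs": list(codebook.forbidden_motifs),
        "rng_seed": codebook.rng_seed,
        "size": len(codebook),
    }
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=2) + "\n"
    )


def read_codebook(path: str | Path) -> BarcodeCodebook:
    path = Path(path)
    members = tuple(
        line.strip() for line in path.read_text().splitlines() if line.strip()
    )
    sidecar_path = path.with_suffix(path.suffix + ".json")
    params = {}
    if sidecar_path.exists():
        params = json.loads(sidecar_path.read_text())
        params.pop("size", None)
    k = params.pop("k", len(members[0]) if members else 12)
    params["forbidden_motifs"] = tuple(params.get("forbidden_motifs", ()))
    return BarcodeCodebook(k=k, members=members, **params)


# ---------------------------------------------------------------------------
# Design tables
# ---------------------------------------------------------------------------

DESIGN_COLUMNS = [
    "pool_id", "oligo_name", "fragment_index", "codon_position",
    "codon_start", "codon_end", "wt_codon", "barcode1", "barcode2",
    "upstream_homology", "downstream_anchor", "fragment_seq",
    "bsai_module", "sequence",
]


def design_to_frame(design: Iterable[OPoolDesign]) -> pd.DataFrame:
    rows = []
    for pool in design:
        frag = pool.fragment
        for oligo in pool.oligos:
            rows.append(
                {
                    "pool_id": pool.pool_id,
                    "oligo_name": oligo.name,
                    "fragment_index": oligo.fragment_index,
                    "codon_position": oligo.codon_position,
                    "codon_start": frag.codon_start,
                    "codon_end": frag.codon_end,
                    "wt_codon": oligo.wt_codon,
                    "barcode1": oligo.barcode_template.barcode1,
                    "barcode2": oligo.barcode_template.barcode2,
                    "upstream_homology": frag.upstream_homology,
                    "downstream_anchor": frag.downstream_anchor,
                    "fragment_seq": frag.fragment_seq,
                    "bsai_module": oligo.bsai_module,
                    "sequence": oligo.sequence,
                }
            )
    return pd.DataFrame(rows, columns=DESIGN_COLUMNS)


def write_design(design: Iterable[OPoolDesign], path: str | Path) -> None:
    write_tsv(design_to_frame(design), path)


def read_design_frame(path: str | Path) -> pd.DataFrame:
    return read_tsv(path, required_columns=DESIGN_COLUMNS)


def fragment_reference_from_frame(
    df: pd.DataFrame, fragment_index: int
) -> FragmentReference:
    """Rebuild the expected-read reference of one fragment from a design
    table (as written by :func:`write_design`)."""
    sub = df[df["fragment_index"] == fragment_index]
    if sub.empty:
        raise KeyError(f"fragment {fragment_index} not in design table")
    first = sub.iloc[0]
    frag_seq = first["fragment_seq"]
    return FragmentReference(
        fragment_index=fragment_index,
        codon_start=int(first["codon_start"]),
        wt_codons=[frag_seq[i : i + 3] for i in range(0, len(frag_seq), 3)],
        downstream_anchor=first["downstream_anchor"],
        bsai_module=first.get("bsai_module", BSAI_MODULE),
        pair_by_position={
            int(r.codon_position): (r.barcode1, r.barcode2)
            for r in sub.itertuples(index=False)
        },
    )


def write_opool_sheet(design: Iterable[OPoolDesign], path: str | Path) -> None:
    """Synthesis order sheet: one CSV row per oligo with IUPAC degeneracies."""
    df = design_to_frame(design)[
        ["pool_id", "oligo_name", "fragment_index", "codon_position", "sequence"]
    ]
    df.to_csv(path, index=False)
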