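"""File I/O helpers: TSV with provenance headers, FASTA, BED, manifest."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Mapping

import pandas as pd


def _version() -> str:
    from importlib.metadata import PackageNotFoundError, version

    try:
        return version("mutspectra")
    except PackageNotFoundError:
        return "unknown"


def write_tsv(df: pd.DataFrame, path, meta: Mapping[str, str] | None = None) -> None:
    """Write a TSV with '#'-prefixed provenance header lines."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# mutspectra_version={_version()}\n")
        for key, value in (meta or {}).items():
            fh.write(f"# {key}={value}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def config_hash(config: Mapping) -> str:
    """Stable short hash of a configuration mapping, for output provenance."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_fasta(sequences: Mapping[str, str], path, width: int = 60) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path) -> dict[str, str]:
    """Load a FASTA into name -> uppercase sequence (small genomes only)."""
    from pyfaidx import Fasta

    with Fasta(str(path), rebuild=True, build_index=True) as fa:
        return {name: str(fa[name][:]).upper() for name in fa.keys()}


def read_bed(path) -> dict[str, list[tuple[int, int]]]:
    """Read a BED file into chrom -> [(start, end)] 0-based half-open."""
    intervals: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            intervals.setdefault(chrom, []).append((start, end))
    return intervals


def read_manifest(path) -> pd.DataFrame:
    """Read a sample manifest TSV with columns sample, subpopulation, continent."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    required = {"sample", "subpopulation", "continent"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing required columns: {sorted(missing)}")
    return df


def manifest_maps(manifest: pd.DataFrame) -> tuple[dict[str, str], dict[str, int]]:
    """(subpopulation -> continent, subpopulation -> sample count) from a manifest."""
    sub_to_cont = (
        manifest.drop_duplicates("subpopulation").set_index("subpopulation")["continent"].to_dict()
    )
    sizes = manifest.groupby("subpopulation")["sample"].count().to_dict()
    return sub_to_cont, sizes
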