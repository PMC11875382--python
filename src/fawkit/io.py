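"""Plain-text interchange: FASTA, metadata/climate/wind CSV, profiles CSV."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import pandas as pd
import xarray as xr
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .markers import ReferenceHaplotypeSet, SpecimenSequence
from .profiles import HaplotypeProfile

__all__ = [
    "write_specimens",
    "read_specimens",
    "write_reference_fasta",
    "read_reference_fasta",
    "read_climate_csv",
    "write_climate_csv",
    "wind_to_csv",
    "wind_from_csv",
    "profiles_to_frame",
]


def write_specimens(
    specimens: Sequence[SpecimenSequence], fasta_path, meta_path
) -> None:
    """Write specimen sequences as FASTA plus a metadata CSV.

    CSV columns: specimen_id, gene, collection_id, state, country, year, type
    (plus any ground-truth metadata the simulator attached).
    """
    records = [
        SeqRecord(Seq(sp.seq), id=f"{sp.specimen_id}|{sp.gene}", description="")
        for sp in specimens
    ]
    SeqIO.write(records, str(fasta_path), "fasta")
    rows = []
    for sp in specimens:
        row = {
            "specimen_id": sp.specimen_id,
            "gene": sp.gene,
            "collection_id": sp.collection_id,
            "state": sp.metadata.get("state", ""),
            "country": sp.metadata.get("country", ""),
            "year": sp.year,
            "type": sp.metadata.get("type", "F"),
        }
        for key in ("true_csh", "true_strain", "heterozygous", "truncated"):
            if key in sp.metadata:
                row[key] = sp.metadata[key]
        if "true_tpi_haps" in sp.metadata:
            row["true_tpi_haps"] = ";".join(sp.metadata["true_tpi_haps"])
        rows.append(row)
    pd.DataFrame(rows).to_csv(meta_path, index=False)


def read_specimens(fasta_path, meta_path) -> list:
    """Read specimen sequences back from FASTA + metadata CSV."""
    meta = pd.read_csv(meta_path).set_index(["specimen_id", "gene"])
    out = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        specimen_id, gene = rec.id.rsplit("|", 1)
        row = meta.loc[(specimen_id, gene)]
        md = {k: row[k] for k in row.index if pd.notna(row[k])}
        if "true_tpi_haps" in md:
            md["true_tpi_haps"] = tuple(str(md["true_tpi_haps"]).split(";"))
        out.append(
            SpecimenSequence(
                specimen_id=specimen_id,
                gene=gene,
                seq=str(rec.seq),
                collection_id=str(row["collection_id"]),
                year=int(row["year"]),
                metadata=md,
            )
        )
    return out


def write_reference_fasta(reference: ReferenceHaplotypeSet, path) -> None:
    """Reference haplotypes as FASTA with the strain in a header tag."""
    records = [
        SeqRecord(Seq(seq), id=f"{label}|strain={strain}", description="")
        for label, seq, strain in reference.entries
    ]
    SeqIO.write(records, str(path), "fasta")


def read_reference_fasta(path, provenance: str = "") -> ReferenceHaplotypeSet:
    entries = []
    for rec in SeqIO.parse(str(path), "fasta"):
        label, tag = rec.id.rsplit("|", 1)
        strain = tag.split("=", 1)[1]
        entries.append((label, str(rec.seq), strain))
    return ReferenceHaplotypeSet(entries=tuple(entries), provenance=provenance or str(path))


def write_climate_csv(weekly: pd.DataFrame, path) -> None:
    weekly.to_csv(path, index=False)


def read_climate_csv(path) -> pd.DataFrame:
    """Weekly climate CSV: columns week, tmin_c, tmax_c, rain_mm[, soil_moisture]."""
    df = pd.read_csv(path)
    required = {"week", "tmin_c", "tmax_c", "rain_mm"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"climate CSV missing columns: {sorted(missing)}")
    return df


def wind_to_csv(wind: xr.Dataset, path) -> None:
    """Wind field to long-format CSV (time, lat, lon, u_ms, v_ms)."""
    wind.to_dataframe().reset_index().to_csv(path, index=False)


def wind_from_csv(path) -> xr.Dataset:
    df = pd.read_csv(path).set_index(["time", "lat", "lon"])
    return xr.Dataset.from_dataframe(df)


def profiles_to_frame(profiles: Sequence[HaplotypeProfile]) -> pd.DataFrame:
    """Long table (collection_id, label, count, freq) for a set of profiles."""
    rows = []
    for p in profiles:
        freqs = p.freqs
        for label in p.labels:
            rows.append(
                {
                    "collection_id": p.collection_id,
                    "label": label,
                    "count": p.counts[label],
                    "freq": freqs.get(label, float("nan")),
                }
            )
    return pd.DataFrame(rows)
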