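"""Readers and writers for the formats the pipeline touches.

FASTA in (Biopython), fixedStep wiggle out for affinity tracks, TSV for
every table (tab-separated, header line always present), BED export for
alleles (conversion to 0-based half-open happens only here), JSON for
synthetic-data truth files.  Coordinates inside the package are 1-based
inclusive throughout.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .deletions import DeletionAllele, MotifDelta, UTRRecord
from .fecundity import BroodDataset
from .motifs import (
    AffinityProfile,
    BindingSite,
    MotifConsensus,
    normalize_sequence,
    parse_consensus,
)
from .profiles import LineProfile, NucCytMeasurement

__all__ = [
    "read_fasta",
    "write_fasta",
    "write_wiggle",
    "read_wiggle",
    "sites_to_frame",
    "write_sites_tsv",
    "profile_to_frame",
    "write_profile_tsv",
    "read_matrix_tsv",
    "write_matrix_tsv",
    "read_catalog_tsv",
    "read_alleles_tsv",
    "write_alleles_bed",
    "delta_to_frame",
    "write_delta_tsv",
    "read_line_profiles_tsv",
    "write_line_profiles_tsv",
    "read_nuccyt_tsv",
    "read_broods_tsv",
    "write_broods_tsv",
    "read_deg_tsv",
    "write_truth_json",
]


def read_fasta(path) -> list[UTRRecord]:
    """Multi-record FASTA → normalized UTR records (T mapped to U).

    The description line is parsed for the id only.  Duplicate ids and
    empty records are errors.
    """
    records: list[UTRRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        if len(rec.seq) == 0:
            raise ValueError(f"empty FASTA record {rec.id!r} in {path}")
        records.append(UTRRecord(utr_id=rec.id, seq=normalize_sequence(str(rec.seq))))
    if not records and Path(path).stat().st_size == 0:
        raise ValueError(f"empty FASTA file {path}")
    return records


def write_fasta(records: Iterable[UTRRecord], path) -> None:
    seq_records = [
        SeqRecord(Seq(r.seq), id=r.utr_id, description="") for r in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")


def write_wiggle(profile: AffinityProfile, path) -> None:
    """fixedStep wiggle (step 1, start 1): one affinity value per position."""
    with open(path, "w") as fh:
        fh.write(f"fixedStep chrom={profile.utr_id} start=1 step=1\n")
        for v in profile.values:
            fh.write(f"{v:.6g}\n")


def read_wiggle(path) -> AffinityProfile:
    """Read back a single fixedStep track written by :func:`write_wiggle`."""
    with open(path) as fh:
        header = fh.readline().split()
        if not header or header[0] != "fixedStep":
            raise ValueError(f"{path}: not a fixedStep wiggle")
        fields = dict(kv.split("=") for kv in header[1:])
        values = [float(line) for line in fh if line.strip()]
    return AffinityProfile(utr_id=fields.get("chrom", "seq"), values=np.array(values))


SITES_COLUMNS = ["utr_id", "start", "end", "spacer_len", "ddg", "krel", "affinity", "perfect"]


def sites_to_frame(sites: Iterable[BindingSite]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "utr_id": s.utr_id, "start": s.start, "end": s.end,
                "spacer_len": s.spacer_len, "ddg": s.ddg, "krel": s.krel,
                "affinity": s.affinity, "perfect": s.perfect,
            }
            for s in sites
        ],
        columns=SITES_COLUMNS,
    )


def write_sites_tsv(sites: Iterable[BindingSite], path) -> None:
    sites_to_frame(sites).to_csv(path, sep="\t", index=False)


def profile_to_frame(profile: AffinityProfile) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "utr_id": profile.utr_id,
            "position": np.arange(1, profile.length + 1),
            "affinity": profile.values,
        }
    )


def write_profile_tsv(profile: AffinityProfile, path) -> None:
    profile_to_frame(profile).to_csv(path, sep="\t", index=False)


def read_matrix_tsv(path) -> "np.ndarray":
    """Penalty matrix TSV (columns position_index, A, C, G, U) → array.

    Rows are ordered by position_index (left half-site first).  The result
    feeds :class:`utrkit.motifs.PenaltyMatrix`.
    """
    df = pd.read_csv(path, sep="\t")
    missing = {"position_index", "A", "C", "G", "U"} - set(df.columns)
    if missing:
        raise ValueError(f"matrix TSV missing columns: {sorted(missing)}")
    df = df.sort_values("position_index")
    return df[["A", "C", "G", "U"]].to_numpy(dtype=float)


def write_matrix_tsv(penalties: "np.ndarray", path) -> None:
    arr = np.asarray(penalties, dtype=float)
    df = pd.DataFrame(arr, columns=["A", "C", "G", "U"])
    df.insert(0, "position_index", np.arange(1, arr.shape[0] + 1))
    df.to_csv(path, sep="\t", index=False)


def read_catalog_tsv(path) -> list[MotifConsensus]:
    """Motif catalog TSV (columns name, pattern).

    Patterns without a spacer token are accepted as single-half-site motifs
    (e.g. the OMA-1/2-associated ``UA(U/A)``).
    """
    df = pd.read_csv(path, sep="\t")
    missing = {"name", "pattern"} - set(df.columns)
    if missing:
        raise ValueError(f"catalog TSV missing columns: {sorted(missing)}")
    return [
        parse_consensus(row.pattern, name=str(row.name_), require_spacer=False)
        for row in df.rename(columns={"name": "name_"}).itertuples(index=False)
    ]


def read_alleles_tsv(path) -> list[DeletionAllele]:
    """Alleles TSV: name, parent_id, start, end (1-based inclusive)."""
    df = pd.read_csv(path, sep="\t")
    missing = {"name", "parent_id", "start", "end"} - set(df.columns)
    if missing:
        raise ValueError(f"allele TSV missing columns: {sorted(missing)}")
    return [
        DeletionAllele(
            name=str(r["name"]), parent_id=str(r["parent_id"]),
            start=int(r["start"]), end=int(r["end"]),
        )
        for _, r in df.iterrows()
    ]


def write_alleles_bed(alleles: Iterable[DeletionAllele], path) -> None:
    """BED export: 0-based half-open (start−1, end)."""
    with open(path, "w") as fh:
        for a in alleles:
            fh.write(f"{a.parent_id}\t{a.start - 1}\t{a.end}\t{a.name}\n")


DELTA_COLUMNS = ["motif", "status", "wt_start", "wt_end", "mut_start", "mut_end", "spacer_len"]


def delta_to_frame(delta: MotifDelta) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "motif": row.motif, "status": row.status,
                "wt_start": row.wt_start, "wt_end": row.wt_end,
                "mut_start": row.mut_start, "mut_end": row.mut_end,
                "spacer_len": row.spacer_len,
            }
            for row in delta.all_rows()
        ],
        columns=DELTA_COLUMNS,
    )


def write_delta_tsv(delta: MotifDelta, path) -> None:
    delta_to_frame(delta).to_csv(path, sep="\t", index=False)


def read_line_profiles_tsv(path) -> list[LineProfile]:
    """Long-format line profiles: animal_id, condition, pixel_index, intensity.

    Pixels are ordered by pixel_index within each animal (distal → proximal).
    """
    df = pd.read_csv(path, sep="\t")
    missing = {"animal_id", "condition", "pixel_index", "intensity"} - set(df.columns)
    if missing:
        raise ValueError(f"profile TSV missing columns: {sorted(missing)}")
    profiles = []
    for (animal, condition), sub in df.groupby(["animal_id", "condition"], sort=True):
        sub = sub.sort_values("pixel_index")
        profiles.append(
            LineProfile(
                animal_id=str(animal), condition=str(condition),
                intensities=sub["intensity"].to_numpy(dtype=float),
            )
        )
    return profiles


def write_line_profiles_tsv(profiles: Iterable[LineProfile], path) -> None:
    frames = [
        pd.DataFrame(
            {
                "animal_id": p.animal_id,
                "condition": p.condition,
                "pixel_index": np.arange(1, p.n_pixels + 1),
                "intensity": p.intensities,
            }
        )
        for p in profiles
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def read_nuccyt_tsv(path) -> list[NucCytMeasurement]:
    """Nuclear/cytoplasmic TSV: animal_id, condition, oocyte_rank (1|2),
    nuclear, cytoplasmic — exactly two ranked oocytes per animal."""
    df = pd.read_csv(path, sep="\t")
    missing = {"animal_id", "condition", "oocyte_rank", "nuclear", "cytoplasmic"} - set(df.columns)
    if missing:
        raise ValueError(f"nuc/cyt TSV missing columns: {sorted(missing)}")
    out = []
    for (animal, condition), sub in df.groupby(["animal_id", "condition"], sort=True):
        sub = sub.sort_values("oocyte_rank")
        if list(sub["oocyte_rank"]) != [1, 2]:
            raise ValueError(f"animal {animal!r}: need oocyte ranks 1 and 2")
        out.append(
            NucCytMeasurement(
                animal_id=str(animal), condition=str(condition),
                nuclear=tuple(sub["nuclear"].astype(float)),
                cytoplasmic=tuple(sub["cytoplasmic"].astype(float)),
            )
        )
    return out


def read_broods_tsv(path) -> dict[str, BroodDataset]:
    """Brood TSV: condition, replicate, animal_id, progeny_count →
    one pooled dataset per condition (replicate labels retained)."""
    df = pd.read_csv(path, sep="\t")
    missing = {"condition", "replicate", "animal_id", "progeny_count"} - set(df.columns)
    if missing:
        raise ValueError(f"brood TSV missing columns: {sorted(missing)}")
    out = {}
    for condition, sub in df.groupby("condition", sort=True):
        out[str(condition)] = BroodDataset(
            condition=str(condition),
            counts=sub["progeny_count"].to_numpy(dtype=int),
            replicates=sub["replicate"].to_numpy(dtype=int),
        )
    return out


def write_broods_tsv(datasets: Iterable[BroodDataset], path) -> None:
    frames = []
    for ds in datasets:
        reps = ds.replicates if ds.replicates is not None else np.ones(ds.n, dtype=int)
        frames.append(
            pd.DataFrame(
                {
                    "condition": ds.condition,
                    "replicate": reps,
                    "animal_id": [f"{ds.condition}_{i + 1}" for i in range(ds.n)],
                    "progeny_count": ds.counts,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def read_deg_tsv(path) -> pd.DataFrame:
    """DE table TSV: gene_id, log2fc, fdr (validated downstream)."""
    df = pd.read_csv(path, sep="\t")
    missing = {"gene_id", "log2fc", "fdr"} - set(df.columns)
    if missing:
        raise ValueError(f"DEG TSV missing columns: {sorted(missing)}")
    return df


def write_truth_json(truth: Mapping | Sequence, path) -> None:
    """Machine-readable ground truth emitted next to synthetic datasets."""
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=2, default=_jsonable)
        fh.write("\n")


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    if hasattr(obj, "__dict__"):
        return obj.__dict__
    raise TypeError(f"not JSON-serializable: {type(obj)}")
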