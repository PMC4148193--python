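"""Readers and writers for the plain-text formats used by every stage.

Internal coordinates are 0-based half-open everywhere (BED convention);
GFF3 input (1-based inclusive) is converted on read.  Readers reject
malformed records with the offending line number rather than silently
repairing them.  Machine outputs go to files; diagnostics go to stderr.
"""

from __future__ import annotations

import json
import sys
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .binding import BindingIsotherm
from .correlation import CorrelationCurve
from .errors import ParseError
from .hic import AggregationProfile, ContactTable, PeakSet

__all__ = [
    "read_bed",
    "write_bed",
    "read_gff3",
    "write_gff3",
    "read_isotherm_tsv",
    "write_isotherm_tsv",
    "read_correlation_tsv",
    "write_correlation_tsv",
    "read_contacts_tsv",
    "write_contacts_tsv",
    "write_profile_tsv",
    "write_json",
    "write_manifest",
]

_BED_SKIP_PREFIXES = ("#", "track", "browser")


def read_bed(path, name: str | None = None) -> PeakSet:
    """Read a BED file into a sorted :class:`PeakSet`.

    Only the first three columns are used; track/browser/comment lines
    are skipped.  Coordinates stay 0-based half-open, so a line
    ``chr3L 264375 264822`` yields an interval of length 447 bp.
    """
    path = Path(path)
    intervals = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(_BED_SKIP_PREFIXES):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError("BED line has fewer than 3 fields", path, lineno)
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise ParseError("non-integer BED coordinates", path, lineno) from None
            if start < 0:
                raise ParseError("negative BED coordinate", path, lineno)
            if start >= end:
                raise ParseError("BED start must be < end", path, lineno)
            intervals.append((chrom, start, end))
    return PeakSet(name=name or path.stem, intervals=intervals)


def write_bed(peaks: PeakSet, path) -> None:
    with Path(path).open("w") as fh:
        for chrom, start, end in peaks.intervals:
            fh.write(f"{chrom}\t{start}\t{end}\n")


def read_gff3(path, name: str | None = None) -> PeakSet:
    """Read GFF3 features into a :class:`PeakSet`.

    GFF3 is 1-based inclusive; intervals are converted to 0-based
    half-open (``start-1``, ``end``), so a feature spanning 1..100 has
    length 100.  Peaks are unstranded: strand information is ignored
    (a notice is printed to stderr when stranded features are present).
    """
    path = Path(path)
    intervals = []
    n_stranded = 0
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(
                    f"GFF3 line has {len(fields)} fields, expected 9", path, lineno
                )
            chrom = fields[0]
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError:
                raise ParseError("non-integer GFF3 coordinates", path, lineno) from None
            if start < 1 or end < start:
                raise ParseError("invalid GFF3 coordinate range", path, lineno)
            if fields[6] in ("+", "-"):
                n_stranded += 1
            intervals.append((chrom, start - 1, end))
    if n_stranded:
        print(
            f"note: ignored strand on {n_stranded} feature(s); peaks are unstranded",
            file=sys.stderr,
        )
    return PeakSet(name=name or path.stem, intervals=intervals)


def write_gff3(peaks: PeakSet, path, source: str = "insulator-bridge",
               feature_type: str = "binding_site") -> None:
    """Write peaks as unstranded GFF3 features (1-based inclusive on disk)."""
    with Path(path).open("w") as fh:
        fh.write("##gff-version 3\n")
        for i, (chrom, start, end) in enumerate(peaks.intervals, start=1):
            fh.write(
                f"{chrom}\t{source}\t{feature_type}\t{start + 1}\t{end}\t.\t.\t.\t"
                f"ID={peaks.name}_{i}\n"
            )


def read_isotherm_tsv(path) -> BindingIsotherm:
    """Read a titration TSV with columns ``conc_nM``, ``anisotropy`` [, ``sigma``]."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#")
    for col in ("conc_nM", "anisotropy"):
        if col not in df.columns:
            raise ParseError(f"missing required column {col!r}", path)
    order = np.argsort(df["conc_nM"].to_numpy())
    df = df.iloc[order]
    sigma = df["sigma"].to_numpy() if "sigma" in df.columns else None
    return BindingIsotherm(
        protein_conc=df["conc_nM"].to_numpy(),
        anisotropy=df["anisotropy"].to_numpy(),
        sigma=sigma,
        label=path.stem,
    )


def write_isotherm_tsv(iso: BindingIsotherm, path) -> None:
    cols = {"conc_nM": iso.protein_conc, "anisotropy": iso.anisotropy}
    if iso.sigma is not None:
        cols["sigma"] = iso.sigma
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)


def read_correlation_tsv(path) -> CorrelationCurve:
    """Read a correlation TSV (columns ``lag_s``, ``G``).

    Channel metadata may appear in a header comment of the form
    ``# channel_pair=cross``.
    """
    path = Path(path)
    channel_pair = "green_auto"
    with path.open() as fh:
        for line in fh:
            if line.startswith("#") and "channel_pair=" in line:
                channel_pair = line.split("channel_pair=")[1].strip()
            if not line.startswith("#"):
                break
    df = pd.read_csv(path, sep="\t", comment="#")
    for col in ("lag_s", "G"):
        if col not in df.columns:
            raise ParseError(f"missing required column {col!r}", path)
    return CorrelationCurve(
        lag=df["lag_s"].to_numpy(), g=df["G"].to_numpy(), channel_pair=channel_pair
    )


def write_correlation_tsv(curve: CorrelationCurve, path) -> None:
    with Path(path).open("w") as fh:
        fh.write(f"# channel_pair={curve.channel_pair}\n")
        fh.write("lag_s\tG\n")
        for lag, g in zip(curve.lag, curve.g):
            fh.write(f"{lag:.9g}\t{g:.9g}\n")


def read_contacts_tsv(path, bin_size: int, genome: dict | None = None) -> ContactTable:
    """Read a contact TSV: columns ``chrom``, ``bin_i_start``, ``bin_j_start``, ``count``.

    When ``genome`` is omitted, chromosome sizes are inferred as the
    largest bin end seen per chromosome.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#")
    required = ["chrom", "bin_i_start", "bin_j_start", "count"]
    for col in required:
        if col not in df.columns:
            raise ParseError(f"missing required column {col!r}", path)
    df = df.rename(columns={"bin_i_start": "bin_i", "bin_j_start": "bin_j"})
    if genome is None:
        ends = pd.concat([
            df.groupby("chrom")["bin_i"].max(),
            df.groupby("chrom")["bin_j"].max(),
        ], axis=1).max(axis=1)
        genome = {c: int(v) + bin_size for c, v in ends.items()}
    return ContactTable(bin_size=bin_size, df=df, genome=dict(genome))


def write_contacts_tsv(table: ContactTable, path) -> None:
    out = table.df.rename(columns={"bin_i": "bin_i_start", "bin_j": "bin_j_start"})
    out.to_csv(path, sep="\t", index=False)


def write_profile_tsv(profile: AggregationProfile, path) -> None:
    """Write an aggregation profile as ``offset_bp  signal  control``."""
    cols = {"offset_bp": profile.offsets, "signal": profile.signal}
    if profile.control is not None:
        cols["control"] = profile.control
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)


class _NumpyEncoder(json.JSONEncoder):
    def default(self, obj):
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, np.bool_):
            return bool(obj)
        return super().default(obj)


def write_json(payload: dict, path) -> None:
    with Path(path).open("w") as fh:
        json.dump(payload, fh, indent=2, cls=_NumpyEncoder)
        fh.write("\n")


def write_manifest(path, subcommand: str, params: dict, seed: int | None = None) -> None:
    """Write a JSON run manifest sufficient to reproduce the run."""
    manifest = {
        "tool": "insulator-bridge",
        "version": __version__,
        "subcommand": subcommand,
        "parameters": params,
        "seed": seed,
    }
    write_json(manifest, path)
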