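"""Readers and writers for the pipeline's on-disk formats.

Image channels are single-page 16-bit grayscale TIFFs (``<field>_dna.tif`` /
``<field>_probe.tif``) with truth as a JSON sidecar; count tables are TSV with
a ``gene_id`` column and ``<condition>_<rep>`` sample columns; promoters are
FASTA with ``planted=0|1`` flags in the header; Ct tables are long-format
CSV/TSV (gene, condition, rep, Ct).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import tifffile
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .fish import ShellComparison, ShellProfile
from .qpcr import CtRecord
from .synthetic import PromoterSet, SyntheticField

__all__ = [
    "write_field",
    "read_channel",
    "write_promoters_fasta",
    "read_promoters_fasta",
    "write_ct_table",
    "read_ct_table",
    "read_gene_list",
    "write_shell_profiles",
    "write_shell_comparison",
    "read_manifest",
]


def write_field(field: SyntheticField, directory, name: str) -> dict[str, Path]:
    """Write DNA/probe TIFFs plus a JSON truth sidecar; returns the paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "dna": directory / f"{name}_dna.tif",
        "probe": directory / f"{name}_probe.tif",
        "truth": directory / f"{name}_truth.json",
    }
    tifffile.imwrite(paths["dna"], field.dna_channel)
    tifffile.imwrite(paths["probe"], field.probe_channel)
    truth = {
        "seed": field.spec.seed,
        "n_nuclei": field.spec.n_nuclei,
        "radial_bias": field.spec.radial_bias,
        "n_shells": field.spec.n_shells,
        "probe_bearing": field.probe_bearing.astype(int).tolist(),
        "truth_shell_fractions": [
            [None if np.isnan(v) else round(float(v), 9) for v in row]
            for row in field.truth_shell_fractions
        ],
    }
    paths["truth"].write_text(json.dumps(truth, indent=1))
    return paths


def read_channel(path) -> np.ndarray:
    return tifffile.imread(path)


def write_promoters_fasta(promoters: PromoterSet, path) -> None:
    records = [
        SeqRecord(
            Seq(seq),
            id=gid,
            description=f"planted={int(gid in promoters.planted)}",
        )
        for gid, seq in promoters.sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_promoters_fasta(path) -> tuple[dict[str, str], frozenset[str]]:
    """Returns (gene_id → sequence, set of planted ids if flagged)."""
    sequences: dict[str, str] = {}
    planted: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        sequences[rec.id] = str(rec.seq).upper()
        if "planted=1" in rec.description:
            planted.add(rec.id)
    return sequences, frozenset(planted)


def write_ct_table(records: Iterable[CtRecord], path, sep: str = "\t") -> None:
    rows = [
        {"gene": r.gene, "condition": r.condition, "rep": i + 1, "Ct": ct}
        for r in records
        for i, ct in enumerate(r.cts)
    ]
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False)


def read_ct_table(path, sep: str | None = None) -> list[CtRecord]:
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    records = []
    for (gene, cond), grp in df.groupby(["gene", "condition"], sort=False):
        cts = tuple(grp.sort_values("rep")["Ct"].astype(float))
        records.append(CtRecord(gene=str(gene), condition=str(cond), cts=cts))
    return records


def read_gene_list(path) -> list[str]:
    """One identifier per line; blank lines ignored; duplicates are an error."""
    ids = [line.strip() for line in Path(path).read_text().splitlines() if line.strip()]
    if len(ids) != len(set(ids)):
        raise ValueError(f"duplicate identifiers in {path}")
    return ids


def write_shell_profiles(profiles: Iterable[ShellProfile], path) -> None:
    rows = []
    for p in profiles:
        for k in range(len(p.ratio)):
            rows.append(
                {
                    "nucleus": p.nucleus_label,
                    "shell": k + 1,
                    "probe_pct": p.probe_pct[k],
                    "dna_pct": p.dna_pct[k],
                    "ratio": p.ratio[k],
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_shell_comparison(cmp: ShellComparison, path) -> None:
    pd.DataFrame(
        {
            "shell": np.arange(1, len(cmp.p) + 1),
            "t": cmp.t,
            "df": cmp.df,
            "p": cmp.p,
            "significant": cmp.significant.astype(int),
        }
    ).to_csv(path, sep="\t", index=False)


def read_manifest(path) -> pd.DataFrame:
    """Field manifest TSV: field_id, dna_path, probe_path, condition."""
    df = pd.read_csv(path, sep="\t")
    required = {"field_id", "dna_path", "probe_path", "condition"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing column(s): {sorted(missing)}")
    return df
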