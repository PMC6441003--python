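"""Generate one demonstration set of every synthetic input class.

Images (TIFF pairs + truth sidecars) go to scratch/demo_fields/; tables
(counts TSV, promoters FASTA, Ct table TSV) to results/data/. All downstream
analysis scripts read these files, so run this first.
"""

from pathlib import Path

from fibroquant import io
from fibroquant.synthetic import (
    CountTableSpec,
    CtTableSpec,
    FieldSpec,
    PromoterSetSpec,
    generate_count_table,
    generate_ct_table,
    generate_nucleus_field,
    generate_promoters,
)

ROOT = Path(__file__).resolve().parent.parent
FIELD_DIR = ROOT / "scratch" / "demo_fields"
DATA_DIR = ROOT / "results" / "data"
SEED = 20_001


def main() -> None:
    DATA_DIR.mkdir(parents=True, exist_ok=True)

    # FISH fields: a peripherally shifted condition vs a uniform control,
    # 2 fields x 50 nuclei each, like one chromosome-paint experiment
    manifest_rows = []
    for cond, beta in (("treated", 3.0), ("control", 0.0)):
        for i in range(2):
            spec = FieldSpec(n_nuclei=50, radial_bias=beta, seed=SEED + 10 * i + int(beta))
            paths = io.write_field(generate_nucleus_field(spec), FIELD_DIR, f"{cond}_{i}")
            manifest_rows.append(
                f"{cond}_{i}\t{paths['dna']}\t{paths['probe']}\t{cond}"
            )
    manifest = FIELD_DIR / "manifest.tsv"
    manifest.write_text(
        "field_id\tdna_path\tprobe_path\tcondition\n" + "\n".join(manifest_rows) + "\n"
    )
    print(f"wrote {len(manifest_rows)} field pairs + {manifest}")

    # count table: 50 genes planted at log2FC 2 in the treated condition
    planted = tuple((f"g{i + 1:04d}", "treated", 2.0) for i in range(50))
    table = generate_count_table(
        CountTableSpec(n_genes=2000, planted_changes=planted, seed=SEED)
    )
    table.to_tsv(DATA_DIR / "counts.tsv")
    print(f"wrote {DATA_DIR / 'counts.tsv'} (2000 genes, 50 planted at log2FC 2)")

    # promoters: 200 x 1050 bp with the synthetic forkhead-like motif in 40%
    promoters = generate_promoters(
        PromoterSetSpec(n_promoters=200, planted_fraction=0.4, seed=SEED)
    )
    io.write_promoters_fasta(promoters, DATA_DIR / "promoters.fasta")
    print(f"wrote {DATA_DIR / 'promoters.fasta'} ({len(promoters.planted)} planted)")

    # Ct table: one target at true FC 2 plus the five-reference panel
    records = generate_ct_table(
        CtTableSpec(targets=(("GOI", 1.0),), noise_sd=0.1, seed=SEED)
    )
    io.write_ct_table(records, DATA_DIR / "ct_table.tsv")
    print(f"wrote {DATA_DIR / 'ct_table.tsv'}")


if __name__ == "__main__":
    main()
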