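#!/usr/bin/env python
"""Replicate-aware differential methylation on the null and alt presets.

Null condition (identical groups): reports the number of genic CpG loci
surviving the 10x every-replicate filter, the estimated per-group
dispersions, and the empirical fraction of loci significant at
alpha = 0.05 (should sit near 0.05).  Alternative condition (20 planted
genic DMRs with a +0.30 methylation difference): reports how many
planted regions are recovered by the area-statistic caller and the
resulting differentially methylated gene (DME) count.

Writes results/dml_null_summary.tsv and results/dme_genes_alt.tsv.
"""

from pathlib import Path

import pandas as pd

from bsmeth.diffmeth import call_dmr, dml_test, map_regions_to_genes
from bsmeth.simulate import preset, simulate_dataset

ROOT = Path(__file__).resolve().parents[1]
SEED = 42


def groups(samples):
    return ([samples[("SA1", r)] for r in (1, 2, 3)],
            [samples[("SAM", r)] for r in (1, 2, 3)])


def main() -> None:
    rows = []
    print("[04] dmr-null: identical groups, phi = 0.02")
    _, ann, samples, _ = simulate_dataset(preset("dmr-null", seed=SEED))
    a, b = groups(samples)
    dml = dml_test(a, b, ann)
    emp = float(dml["significant"].mean())
    regions = call_dmr(dml)
    rows.append({"condition": "null", "n_loci": dml.attrs["n_filtered"],
                 "phi_a": round(dml.attrs["phi_a"], 4),
                 "phi_b": round(dml.attrs["phi_b"], 4),
                 "frac_significant": round(emp, 4),
                 "n_dmr": len(regions)})
    print(f"     {dml.attrs['n_filtered']} genic CpG loci at >=10x in all six "
          f"replicates; {emp:.4f} significant at alpha=0.05; "
          f"{len(regions)} regions called")

    print("[04] dmr-alt: 20 planted genic DMRs, +0.30 difference in SAM")
    cfg = preset("dmr-alt", seed=SEED)
    _, ann, samples, _ = simulate_dataset(cfg)
    a, b = groups(samples)
    dml = dml_test(a, b, ann)
    regions = call_dmr(dml)
    recovered = 0
    for planted in cfg.dmrs:
        if any(r.contig == planted.contig and r.start - 1 < planted.end
               and r.end > planted.start for r in regions):
            recovered += 1
    genes = map_regions_to_genes(regions, ann)
    rows.append({"condition": "alt", "n_loci": dml.attrs["n_filtered"],
                 "phi_a": round(dml.attrs["phi_a"], 4),
                 "phi_b": round(dml.attrs["phi_b"], 4),
                 "frac_significant": round(float(dml["significant"].mean()), 4),
                 "n_dmr": len(regions)})
    print(f"     {recovered}/20 planted DMRs overlapped by a call; "
          f"{len(regions)} regions -> {len(genes)} DMEs")

    outdir = ROOT / "results"
    outdir.mkdir(exist_ok=True)
    pd.DataFrame(rows).to_csv(outdir / "dml_null_summary.tsv", sep="\t", index=False)
    genes.to_csv(outdir / "dme_genes_alt.tsv", sep="\t", index=False)
    print(f"[04] wrote {outdir / 'dml_null_summary.tsv'} and "
          f"{outdir / 'dme_genes_alt.tsv'}")


if __name__ == "__main__":
    main()
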