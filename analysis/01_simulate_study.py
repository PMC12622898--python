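"""Simulate the synthetic study and write the on-disk fixture.

132 inbred accessions in 3 latitudinal subpopulations, 5000 biallelic SNPs
on chromosomes 1-6 plus the unanchored group "0", two clinal causal loci at
joint r2 0.6, polygenic background to total genetic variance 0.9, three
replicate plants per accession, censoring at 200 days.
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
import common  # noqa: E402
from clineflower import simulate  # noqa: E402


def main():
    common.ensure_dirs()
    g, pheno, truth, ann = common.study_data()
    fix_dir = common.SCRATCH / "study_data"
    paths = simulate.write_fixture(
        g, pheno, ann, truth, fix_dir,
        contig_lengths=simulate.chromosome_lengths(common.STUDY))

    n_censored = int((~pheno.drop_duplicates("accession")["flowered"]).sum())
    summary = {
        "n_accessions": common.STUDY.n_accessions,
        "n_snps": common.STUDY.n_snps,
        "n_censored_accessions": n_censored,
        "causal_snp_ids": truth.causal_snp_ids,
        "causal_effects_days_per_dose": truth.causal_effects,
        "realized_variance_fractions": truth.realized_mean_scale_fractions,
    }
    out = common.RESULTS / "simulation_truth.json"
    out.write_text(json.dumps(summary, indent=2) + "\n")

    print(f"wrote fixture to {fix_dir} ({[p.name for p in paths.values()]})")
    print(f"{n_censored} of {common.STUDY.n_accessions} accessions censored "
          f"at {common.STUDY.censor_days:.0f} days")
    print(f"causal loci: {truth.causal_snp_ids} "
          f"(effects {[round(e, 2) for e in truth.causal_effects]} days/dose)")
    print(f"realized variance fractions: "
          f"{ {k: round(v, 3) for k, v in truth.realized_mean_scale_fractions.items()} }")
    print(f"summary -> {out}")


if __name__ == "__main__":
    main()
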