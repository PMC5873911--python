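"""Simulate a serial-allograft tumor cohort and write it as plain-text files.

Builds a 20 Mb toy genome (six arms plus a short Y proxy region), evolves one
tumor line through T0 -> T5 -> T10 with per-passage CNV/SNP birth and
retention, draws binned coverage for every sample, and writes bedGraph
coverage, BED truth intervals, a truth VCF and a sample sheet.
"""

import tumorgi as tgi

cfg = tgi.SimConfig(seed=7)
model, truth, coverages = tgi.simulate_cohort(cfg)

print(f"genome: {len(model.chrom_names)} arms, "
      f"{sum(model.chrom_lengths.values()) / 1e6:.1f} Mb, "
      f"{model.n_bins_total} bins of {model.bin_size} bp")
print(f"UR intervals: {len(model.ur_intervals)} "
      f"({(model.ur_intervals.end - model.ur_intervals.start).sum() / 1e6:.2f} Mb)")
for s in truth.samples:
    n_cnv = len(truth.cnvs_for(s.sample_id)) if s.role == "tumor" else 0
    n_snp = len(truth.snps_for(s.sample_id)) if s.role == "tumor" else 0
    print(f"  {s.sample_id:14s} {s.role:8s} T{s.timepoint:<3d} "
          f"{n_cnv:3d} CNVs {n_snp:4d} SNPs "
          f"mean coverage {coverages[s.sample_id].mean():.1f}x")

manifest = tgi.io.write_fixture_set("scratch/example_cohort", model, truth, coverages)
print(f"\nwrote {len(manifest)} files under scratch/example_cohort/")
print("CNV and SNP counts grow with passage because each allograft round")
print("brings new lesions while only a fraction of old ones is retained.")
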