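"""Work with the bundled per-sample sequencing summary of the study.

Seventeen size-fractionated (0.2-1.6 um) marine metagenomes: surface,
deep-chlorophyll-maximum and oxygen-minimum-zone casts.  Densities in this
package are always per Mbp of these totals.
"""

from ncldvscope.datasets import load_top_sample_table, total_sequenced_bp

df = load_top_sample_table()
print(df[["sample_id", "depth_zone", "total_bp", "n_reads"]].to_string(index=False))
print(f"\ntotal sequenced: {total_sequenced_bp() / 1e9:.2f} billion bp "
      f"({df['n_reads'].sum() / 1e6:.1f} million reads)")
# The summed totals reproduce the data set's published overall size
# (~2.8 billion bp from ~8 million pyrosequencing reads).
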