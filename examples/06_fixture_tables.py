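"""Tally the packaged in-print tables.

The package ships the printed candidate temperature-responsive gene
table (41 entries, one with an infinite fold change because the
transcript is undetected before the shift) and the candidate-regulator
table (25 unique genes across per-interval comparisons).
"""

from tsdnet import load_table1_fixture, load_table2_fixture, summarize_table1, summarize_table2

t1 = load_table1_fixture()
print("temperature-responsive table:", summarize_table1(t1))
infinite = next(r for r in t1 if r.is_infinite)
print(f"infinite fold change: {infinite.description} ({infinite.accession})")

t2 = load_table2_fixture()
summary = summarize_table2(t2)
print("candidate regulators:", {k: summary[k] for k in
      ("n_records", "unique_genes", "transcription_factors")})
print("records per molecule type:", summary["records_per_molecule_type"])
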