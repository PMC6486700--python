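"""Target-decoy FDR filtering of engine-level PSM tables, then merging.

Builds a tiny two-engine search result in memory, filters each engine's
stratum at 1% FDR, and merges the survivors into one identification set.
"""

import io

from metaprofiler import filter_by_fdr, merge_engines, read_psm_table

ENGINE_A = """\
spectrum_key\tsample_id\tengine\tpeptide\tscore\taccessions\tis_decoy
s1\tBGP01\tengineA\tLVGELAK\t42.0\tP1\t0
s2\tBGP01\tengineA\tAATFGLK\t38.5\tP2;P3\t0
s3\tBGP01\tengineA\tMMIRTEK\t11.0\tREV_P9\t1
s4\tBGP01\tengineA\tGGSPFAK\t9.5\tP4\t0
"""

ENGINE_B = """\
spectrum_key\tsample_id\tengine\tpeptide\tscore\taccessions\tis_decoy
s1\tBGP01\tengineB\tLVGELAK\t55.0\tP1\t0
s5\tBGP01\tengineB\tTTIDWNK\t47.2\tP5\t0
"""

filtered = [
    filter_by_fdr(read_psm_table(io.StringIO(text)), fdr_target=0.01)
    for text in (ENGINE_A, ENGINE_B)
]
merged = merge_engines(filtered)

print(f"records after merge: {len(merged)}")
print(f"distinct spectra:    {len(merged.distinct_spectra())}")
for record in merged.records:
    print(f"  {record.spectrum_key}  {record.peptide:8s} "
          f"engines={','.join(record.engines)}  score={record.score}")
# s1 was identified identically by both engines, so it collapses to one
# record tagged with both; every decoy is gone and the realized
# decoy/target ratio at the chosen score threshold is at most 1%.
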