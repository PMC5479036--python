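"""Translate coding sequences and inspect the similarity screen.

Nucleotide datasets are translated in frame 1 with the standard code;
sequences with ambiguous reading frames or premature stops are rejected
and reported. The screening step then shows how the length-dependent
identity threshold (the twilight-zone curve) decides which hits count as
similar.
"""

from orthored import SequenceRecord, rost_threshold, translate_cds

cds = [
    SequenceRecord("SP1|ok", "SP1", "ATGAAAGTTCTGCATGAAGCAGGTTAA"),
    SequenceRecord("SP1|premature", "SP1", "ATGTAAAAAGTTCTG"),
    SequenceRecord("SP1|frameshift", "SP1", "ATGAAAGT"),
    SequenceRecord("SP2|ambiguous", "SP2", "ATGNNNGTT"),
]
dataset, rejected = translate_cds(cds)

print("translated:")
for rec in dataset:
    print(f"  {rec.seq_id:16s} -> {rec.residues}")
print("rejected:")
for seq_id, reason in rejected:
    print(f"  {seq_id:16s} -> {reason}")

print("\nminimum %identity for a hit to count as similar, by alignment length:")
for L in (11, 25, 80, 200, 450, 1000):
    print(f"  L = {L:4d}  ->  {rost_threshold(L):6.1f}%")
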