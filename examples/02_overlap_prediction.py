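"""Will 2 x 300 nt paired reads overlap on each amplicon?

The sequenced product is forward primer + amplicon + reverse primer; reads
overlap geometrically when 2*read_len - product >= min_overlap. A positive
prediction can still fail in practice when quality truncation shortens the
reads, so the pipeline always decides per read pair empirically.
"""

from ampliqc.config import default_markers, predict_read_overlap

print(f"{'marker':<10} {'amplicon':>8} {'product':>8} {'overlap?':>9}")
for mk in default_markers():
    pred = predict_read_overlap(mk, read_len=300, min_overlap=10)
    print(f"{mk.name:<10} {mk.expected_amplicon_len:>8} "
          f"{mk.sequenced_product_len:>8} {'yes' if pred else 'no':>9}")
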