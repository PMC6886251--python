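"""Generate a staged expression dataset and run the preprocessing steps.

Builds a small six-stage (Q20..Q175) dataset with planted differential
genes, writes it to disk, reads it back, and applies the standard filters:
drop unexpressed genes, keep high-variance genes, z-score each sample.
"""

import tempfile
from pathlib import Path

from weakde import (SynthConfig, filter_low_variance, filter_unexpressed,
                    generate, normalize_samples, read_expression_table,
                    write_fixture)

cfg = SynthConfig(seed=1, n_genes=400, n_de_late=20, n_de_mid=20,
                  n_de_shared=20, n_labeled_pos=25, n_labeled_neg=120)
x, truth = generate(cfg)
print(f"generated {x.n_genes} genes x {x.n_samples} samples, "
      f"stages {x.q_order}")
print(f"planted DE genes: {len(truth.de_all)} "
      f"({len(truth.disease_genes)} flagged disease-related)")

with tempfile.TemporaryDirectory() as tmp:
    paths = write_fixture(x, truth, Path(tmp))
    back = read_expression_table(paths["expression"])
    print(f"round-tripped through {paths['expression'].name}: "
          f"{back.n_genes} genes")

x = filter_unexpressed(back)          # drops genes that are zero everywhere
x = filter_low_variance(x, keep=300)  # keeps the 300 most variable genes
x = normalize_samples(x)              # z-scores every sample column
print(f"after preprocessing: {x.n_genes} genes; "
      f"column means ~{x.values.mean(axis=0).max():.1e}, "
      f"sds ~{x.values.std(axis=0).mean():.3f}")
# Each sample now has mean 0 / sd 1, so between-sample depth differences
# cannot masquerade as differential expression.
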