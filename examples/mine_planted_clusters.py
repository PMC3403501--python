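"""Mine a simulated network collection with a known planted cluster.

Generates the reference benchmark (200 exons x 20 networks, background
mean 0.1, one 10-exon pattern recurring in 8 networks at heaviness 0.7),
runs the tensor miner with the default norm parameters (p=0.8, alpha=0.2,
q=10), and scores recovery against the ground truth.
"""

from cosplice import MiningConfig, default_benchmark, mine_all, score_recovery

bench = default_benchmark(seed=42)
truth = bench.planted[0]
print(f"planted: {len(truth.exon_ids)} exons x {len(truth.network_ids)} networks "
      f"at heaviness {truth.spec.target_heaviness}")

clusters = mine_all(bench.tensor, MiningConfig(seed=42, max_patterns=2))
for j, c in enumerate(clusters):
    print(f"cluster {j}: {len(c.exon_ids)} exons, recurrence {c.recurrence}, "
          f"heaviness {c.heaviness:.3f}")

report = score_recovery(clusters[:1], bench)
print(f"exon Jaccard {report.exon_jaccard[0]:.2f}, "
      f"network Jaccard {report.network_jaccard[0]:.2f}, "
      f"detected: {report.detected[0]}")
print(
    "A Jaccard of 1.00/1.00 means the first mined cluster is exactly the"
    " planted exon set in exactly the planted networks; the background"
    " (mean weight 0.1) offers no pattern above the heaviness threshold 0.4."
)
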