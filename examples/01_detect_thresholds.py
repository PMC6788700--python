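"""Detect outcome-enriched thresholds on a synthetic clinical-style table.

Plants one known cutpoint (values below the 20th percentile carry an
80% outcome rate vs 20% elsewhere), runs detection, and prints the
recovered thresholds next to the ground truth.
"""

from ufa import (
    GeneratorConfig,
    PlantedThresholdSpec,
    detect_thresholds,
    generate,
)

config = GeneratorConfig(
    n=2000,
    seed=42,
    planted=(
        PlantedThresholdSpec("temperature", "below", tail_rate=0.8, cut_quantile=0.2),
    ),
    n_noise=3,
    base_rate=0.2,
)
data, truth = generate(config)
print(f"planted: {truth[0].variable} {truth[0].side} cut={truth[0].cut:.4f}")

thresholds = detect_thresholds(data)
for t in thresholds:
    print(
        f"detected: {t.variable:12s} {t.side:5s} cut={t.cut:.4f} "
        f"Z={t.z:+.2f} tail rate={t.p_out:.2f} vs IQR rate={t.baseline.p_iqr:.2f} "
        f"(support {t.n_out})"
    )
    print("  " + t.rule_text("death"))

# The detected cut should sit within one candidate-grid spacing of the
# planted 0.2; |Z| far above the 2.576 critical value reflects the strong
# planted enrichment (0.8 vs 0.2). Noise variables rarely appear: the
# scan's false-detection rate per variable side is a few percent.
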