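"""The five-trial batch qualification protocol, at reduced size.

Five independent scenes are generated, counted, and aggregated into
per-trial accuracies plus the cumulative counting error of the summed
batch.  The full-size protocol (300 kernels per trial) is what
scripts/acceptance.py runs; here 60 kernels per trial keep the example
quick while exercising the identical code path.
"""

from kernelflow import PipelineConfig, SimConfig, replicate_trials

config = PipelineConfig(sim=SimConfig(n_kernels=60))
summary = replicate_trials(config, seeds=[1, 2, 3, 4, 5])

for t in summary["trials"]:
    print(f"trial {t['trial']} (seed {t['seed']}): "
          f"{t['predicted_count']}/{t['true_count']} counted "
          f"-> {t['accuracy_display']}% ({t['id_switches']} id switches)")
print(f"\ntotal {summary['total_predicted']}/{summary['total_true']} "
      f"-> cumulative error {summary['cumulative_error_pct']:.2f}%")
# The cumulative error can beat every per-trial accuracy because over-
# and under-counts across trials partially cancel in the summed batch.
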