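"""Train the SHCFTT classifier under the 70/30 protocol.

Uses pooled single-treatment scenes (one plot per acquisition, the field
campaign geometry), SuperPCA reduction, and the default architecture:
3x3x7 / 3x3x5 / 3x3x3 3-D convolutions (8/16/32 kernels), a 64-kernel 2-D
convolution with CBAM, a Gaussian-initialized feature tokenizer and one
transformer encoder block.  Takes a few minutes on one CPU.
"""

from canopyhsi.experiments import standard_protocol
from canopyhsi.simulate import SceneConfig
from canopyhsi.train import TrainConfig

result = standard_protocol(SceneConfig(separability=2.0), seed=3,
                           hp=TrainConfig(epochs=25, seed=3))
print(f"train: n={result['n_train']}  "
      f"OA {100*result['train']['OA']:.2f}%  AA {100*result['train']['AA']:.2f}%")
print(f"test:  n={result['n_test']}  "
      f"OA {100*result['test']['OA']:.2f}%  AA {100*result['test']['AA']:.2f}%  "
      f"Kappa(x100) {result['test']['Kappa_x100']:.2f}")
# With well-separated treatments the model recovers all 14 classes on
# held-out pixels; accuracies at or near 100% match the separable regime.
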