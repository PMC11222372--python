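"""Build DSNet variants and inspect the architecture contracts:
channel schedule, token counts, attention gates, output shapes."""

import numpy as np

from hipposeg import DSNet, ModelConfig, resolve_preset, stage5_token_count
from hipposeg.nn import Tensor

cfg = ModelConfig()
print("encoder channels:", [cfg.stage_channels(l) for l in range(1, 6)])
print("tokens at stage 5 for a 128^3 patch:", stage5_token_count((128,) * 3))

run = resolve_preset("dsnet-tiny")
model = DSNet(run.model, seed=0)
x = np.random.default_rng(0).normal(size=(1, 2, 32, 32, 32)).astype(np.float32)
binary, subfield = model(x)
print(f"tiny model: {model.n_parameters():,} parameters; "
      f"binary logits {binary.shape}, subfield logits {subfield.shape}")

tokens = Tensor(np.random.default_rng(1).normal(size=(1, 8, 32)))
att = model.transformers[5].blocks[0].msa.attention_weights(tokens)
print(f"attention rows sum to 1: {np.allclose(att.sum(-1), 1.0)}")

for name in ("dsnet-no-cbam", "dsnet-no-transformer", "dsnet-single-branch"):
    r = resolve_preset(name)
    r.model.base_channels, r.model.token_dim, r.model.n_heads = 4, 32, 2
    m = DSNet(r.model, seed=0)
    b, s = m(x[:, : r.model.in_channels])
    print(f"{name:22s} -> binary={'None' if b is None else tuple(b.shape)}, "
          f"subfield={tuple(s.shape)}, params={m.n_parameters():,}")
# The ablation flags reproduce the architecture variants: removing the
# dual branch drops the binary output and its parameters.
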