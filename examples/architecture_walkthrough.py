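"""Instrumented forward pass of the full-size network.

Builds the 224 x 224 bilateral model, pushes one random image through it,
and prints the output shape of every stage next to the designed value.
Each line should read "ok": the semantic branch halves resolution and
doubles channels three times (56x56x96 -> 7x7x768), the detail branch
descends 224 -> 14 through depthwise-separable bottlenecks, and the decoder
climbs back to a 224x224x1 logit map.
"""

import numpy as np

from irisseg import IrisSegNet, ModelConfig

model = IrisSegNet(ModelConfig(random_seed=0))
image = np.random.default_rng(0).random((1, 3, 224, 224), dtype=np.float32)
trace = model.shape_trace(image)
expected = model.config.layer_shapes()

print(f"parameters: {model.num_parameters():,}")
for name, want in expected.items():
    got = trace[name]
    status = "ok" if got == want else f"MISMATCH (want {want})"
    print(f"{name:32s} {str(got):>16s}  {status}")
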