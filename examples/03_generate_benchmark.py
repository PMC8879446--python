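"""Build the bundled 3-domain class-incremental benchmark and inspect it."""

import numpy as np

from mutualcl import default_benchmark

tasks = default_benchmark(seed=0)

print(f"{len(tasks.increments)} increments, {len(tasks.registry)} registry classes")
for k, inc in enumerate(tasks.increments):
    counts = {c.split('/')[1]: inc.train_y.count(c) for c in inc.classes}
    print(f"  increment {k}: domain={inc.domain:13s} "
          f"train={len(inc.train_x):3d} test={len(inc.test_x):3d} "
          f"train counts={counts}")
x, y = tasks.cumulative_test(2)
print(f"cumulative test set after increment 3: {len(y)} samples")
print("Domains emulate grayscale/color baggage screening plus a retinal set;")
print("'multiple' composites several contraband shapes, 'normal' holds only")
print("distractor texture, and the 20/80 split keeps training sets small.")
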