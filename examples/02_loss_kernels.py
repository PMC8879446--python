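"""Evaluate the four objectives L_N, L_O, L_MD and L_CL on one small batch."""

import numpy as np

from mutualcl import (
    LabelIndicator,
    SoftRepresentation,
    continual_loss,
    mutual_distillation_loss,
    new_knowledge_loss,
    old_knowledge_loss,
    soften,
)
from mutualcl.gaussian_bayes import PosteriorTable

rng = np.random.default_rng(1)
n, w, tau = 4, 3, 2.0

logits = rng.normal(0, 2, (n, w))
student = soften(logits, tau)                       # acquisition stream
teacher = SoftRepresentation(rng.dirichlet(np.ones(w), n), tau, "old")
onehot = LabelIndicator.from_indices([0, 1, 2, 0], w)

lp = rng.normal(0, 1, (n, w))
lp -= np.log(np.exp(lp).sum(axis=1, keepdims=True))  # a class posterior table
table = PosteriorTable(lp.copy(), lp, list(range(w)))

l_n = new_knowledge_loss(onehot, student, n)
l_o = old_knowledge_loss(onehot, teacher, n)
l_md = mutual_distillation_loss(None, onehot, None, table, tau)
b = continual_loss(l_n, l_md, l_o, tau)

print(f"L_N  (acquisition, KL)          = {b.l_n:.4f}")
print(f"L_O  (retention, cross-entropy) = {b.l_o:.4f}")
print(f"L_MD (mutual distillation)      = {b.l_md:.4f}")
print(f"L_CL = L_N + L_MD + L_O         = {b.l_cl:.4f}")
print("L_MD is the 1/tau^2-scaled cross-entropy of the true labels against")
print("the joint-representation class posterior; L_CL is their plain sum.")
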