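"""One-off generator for the packaged stand-in Dirichlet mixture files."""
import numpy as np
from Bio.Align import substitution_matrices

AA = "ACDEFGHIKLMNPQRSTVWY"
# Robinson & Robinson background frequencies
P = np.array([0.07805,0.01925,0.05364,0.06295,0.03856,0.07377,0.02199,0.05142,
              0.05744,0.09019,0.02243,0.04487,0.05203,0.04264,0.05129,0.07120,
              0.05841,0.06441,0.01330,0.03216])
P = P / P.sum()

B = substitution_matrices.load("BLOSUM62")
S = np.array([[B[a][b] for b in AA] for a in AA], dtype=float)
# conditional substitution profiles q(b|a) ~ p_b * 2^(s_ab/2)
cond = P[None, :] * 2.0 ** (S / 2.0)
cond /= cond.sum(axis=1, keepdims=True)

def comp_lines(rho, alpha):
    out = []
    for r, a in zip(rho, alpha):
        out.append(" ".join([f"{r:.6f}"] + [f"{x:.6f}" for x in a]))
    return out

def write(fname, rho, alpha, title):
    rho = np.asarray(rho); rho = rho / rho.sum()
    lines = [f"# {title}", f"# residues in order {AA}", str(len(rho))] + comp_lines(rho, alpha)
    with open(fname, "w") as fh:
        fh.write("\n".join(lines) + "\n")

# 20-component: one substitution-profile component per residue, |alpha| = 2.5
write("/root/pkg/src/gibbsmsa/data/dm20.txt", P, 2.5 * cond,
      "compact 20-component mixture (substitution profiles, |alpha|=2.5)")

# 58-component: two concentration tiers per residue + 17 residue-group
# components + one near-uniform component
groups = ["AG","ST","NQ","DE","KR","HKR","ILV","FY","FWY","MILV","CST","DN",
          "EQ","SA","TV","AILMV","KRQE"]
rows = []
rhos = []
for c, w in ((1.2, 0.45), (8.0, 0.45)):
    for i in range(20):
        rows.append(c * cond[i]); rhos.append(w * P[i])
for g in groups:
    idx = [AA.index(ch) for ch in g]
    prof = P * 0.2
    for i in idx:
        prof = prof + cond[i] * P[i]
    prof = prof / prof.sum()
    rows.append(3.0 * prof); rhos.append(0.09 / len(groups))
rows.append(0.8 * np.ones(20)); rhos.append(0.01)
write("/root/pkg/src/gibbsmsa/data/dm58.txt", rhos, np.array(rows),
      "58-component mixture (two tiers + residue groups + uniform)")
print("ok")
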