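"""One-off generator for the synthetic fixture germline set (fixed seed)."""
import numpy as np

rng = np.random.default_rng(20160)
BASES = np.array(list("ACGT"))

def rand_seq(n):
    return "".join(rng.choice(BASES, size=n))

def write(path, entries):
    with open(path, "w") as fh:
        for name, seq, anchor in entries:
            hdr = name if anchor is None else f"{name}|anchor={anchor}"
            fh.write(f">{hdr}\n{seq}\n")

# V: 96 nt, conserved cysteine codon TGT at 84..86
vs = []
for i in range(6):
    s = rand_seq(96)
    s = s[:84] + "TGT" + s[87:]
    vs.append((f"IGHVS-{i+1}*01", s, 84))
# D: 16 nt, no anchor
ds = [(f"IGHDS-{i+1}*01", rand_seq(16), None) for i in range(3)]
# J: 27 nt, conserved tryptophan codon TGG at 12..14
js = []
for i in range(4):
    s = rand_seq(27)
    s = s[:12] + "TGG" + s[15:]
    js.append((f"IGHJS-{i+1}*01", s, 12))

write("src/clonalfam/data/v_synthetic.fasta", vs)
write("src/clonalfam/data/d_synthetic.fasta", ds)
write("src/clonalfam/data/j_synthetic.fasta", js)
print("written")
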