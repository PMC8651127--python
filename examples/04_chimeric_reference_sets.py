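"""Build reference sets with a controlled proportion of chimeras.

Chimeric references (two-parent splices) distort downstream read mapping
and differential-expression calls; this generator produces graded
reference sets for studying that effect.
"""
from levelasm import make_chimeric_references, make_toy_transcriptome

transcripts = make_toy_transcriptome("simple", seed=21, k=15, n=10, length=600)
for proportion in (0.0, 0.2, 0.5):
    refs = make_chimeric_references(transcripts, proportion, seed=21)
    chimeras = [r for r in refs if r.id.startswith("chimera_")]
    print(f"proportion {proportion:.1f}: {len(refs)} references, "
          f"{len(chimeras)} chimeric")
    for c in chimeras[:2]:
        _, p1, p2 = c.id.split("|")
        print(f"  {len(c.sequence)} nt splice of {p1} + {p2}")
# record ids keep both parent ids, so every chimera is traceable when
# evaluating its effect on mapping or expression analysis.
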