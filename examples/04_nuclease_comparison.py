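"""Compare single-strand nucleases at removing end-repair artifacts.

The same fragment pool is digested with each enzyme model before end
repair. The S1 model (overhangs + gaps + nicks) removes almost all
artifacts; mung bean (weak at nicks) leaves a few; RecJf (5' overhangs
only) leaves every gap- and nick-borne lesion behind.
"""
import ssduplex as sx
from ssduplex.truth import artifact_recovery

baseline = None
for model, units in (("none", 0), ("s1", 100), ("mbn", 100), ("recjf", 100)):
    cfg = sx.SimConfig()
    cfg.genome.length = 50_000
    cfg.shear.n_fragments = 4000
    cfg.nuclease.model = model
    cfg.nuclease.units = units
    res = sx.simulate(cfg, seed=4)
    dcs = sx.call_consensus(sx.records_from_library(res.library))
    ar = artifact_recovery(dcs, res.library.truth_variants)
    if baseline is None:
        baseline = max(ar.n_called, 1)
        print(f"{model:6s} (untreated): {ar.n_called} artifact calls")
    else:
        print(f"{model:6s} {units:>4} U: {ar.n_called:4d} artifact calls "
              f"({100 * (1 - ar.n_called / baseline):.1f}% removed)")
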