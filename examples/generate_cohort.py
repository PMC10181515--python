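"""Generate one synthetic subject per phenotype and inspect its indices.

The generator places apneic minutes with a Markov chain, modulates the RR
series (brady-tachycardia cycles in apneic minutes, respiratory sinus
arrhythmia elsewhere) and adds saw-tooth SpO2 desaturations for
desaturating subjects only.
"""

from apneascreen import synth_record
from apneascreen.synthetic import for_group

for group in ("control", "desaturating", "non_desaturating"):
    rec = synth_record(for_group(group, seed=7))
    print(
        f"{group:18s} minutes={rec.n_minutes}  apneic={rec.labels.n_apnea:3d}  "
        f"AHI={rec.ahi_manual:5.2f}/h  ODI={rec.odi_manual:5.2f}/h"
    )

# AHI is the apneic-minutes-per-hour proxy; ODI counts >=3% desaturations
# per hour.  Note the non-desaturating subject: high AHI, ODI < AHI/2 --
# its apneas barely show in the oximetry at all.
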