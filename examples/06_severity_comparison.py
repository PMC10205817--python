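"""Trans-coarctation gradient vs suture wire diameter at fixed cardiac output.

Simulates the same network with the stenosis throat set by each wire
diameter (2.6, 2.0, 1.6 mm against a 5.66 mm reference) and reports the
peak-to-peak gradient across the coarctation.
"""

import numpy as np

from coasim.rom import RomNetwork, Segment, Stenosis, simulate
from coasim.waveform import generate_flow_waveform
from coasim.windkessel import WindkesselOutlet

seg_kw = dict(length_cm=2.0, r_dia_cm=0.3, h_cm=0.03, e_dyn_cm2=1.9e6)
a0 = np.pi * (0.05 * 5.66) ** 2

for wire_mm in (2.6, 2.0, 1.6):
    sten = Stenosis(a_s_cm2=np.pi * (0.05 * wire_mm) ** 2, a_0_cm2=a0, l_s_cm=0.8)
    net = RomNetwork(
        inflow=generate_flow_waveform(6.18, 220, 1),
        segments=(Segment(name="a", **seg_kw),
                  Segment(name="coa", stenosis=sten, **seg_kw),
                  Segment(name="c", **seg_kw)),
        outlets={"arch": WindkesselOutlet(3.6, 32.4, 0.025),
                 "desc": WindkesselOutlet(1.25, 11.2, 0.071)},
        outlet_nodes={"arch": 1, "desc": 3},
    )
    sol = simulate(net)
    bpg = sol.node_pressure[1].max() - sol.node_pressure[3].max()
    v_jet = np.abs(sol.segment_flow[1]).max() / sten.a_s_cm2
    print(f"wire {wire_mm} mm: BPG_pp {bpg:6.1f} mmHg, jet velocity {v_jet:6.0f} cm/s")
# The gradient rises steeply as the wire narrows -- the severity ordering the
# clinical le10 / 10to20 / ge20 classification rests on.
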