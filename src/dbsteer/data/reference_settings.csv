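subject,hemisphere,arm,amplitude_mA,frequency_Hz,pulse_width_us,electrode_configuration,stimulation_mode
0309-005,left,soc,3.5,159,60,"E2: -100%",directional
0309-005,left,agp,2.8,130,60,"E1: -100%",ring
0309-005,right,soc,2.5,159,60,"E5: -100%",directional
0309-005,right,agp,2.9,130,60,"E2: -8%, E4: -22%, E5: -18%, E7: -52%",directional
0309-006,left,soc,3.7,159,60,"E2: -100%",directional
0309-006,left,agp,3.5,130,60,"E1: -100%",ring
0309-006,right,soc,2.0,159,60,"E7: -100%",directional
0309-006,right,agp,4.3,130,60,"E5: -8%, E6, E7: -6%, E8: -80%",ring
0309-007,left,soc,2.1,130,60,"E5: -100%",directional
0309-007,left,agp,2.7,130,60,"E5: -60%, E8: -40%",directional
0309-007,right,soc,2.2,130,60,"E3: -100%",directional
0309-007,right,agp,3.5,130,60,"E1: -50%, E2: -12%, E4: -38%",directional
0309-008,left,soc,2.7,185,60,"E2: -34%, E3, E4: -33%",ring
0309-008,left,agp,5.0,130,60,"E2: -2%, E4: -8%, E5: -22%, E7: -68%",directional
0309-008,right,soc,1.0,185,60,"E2: -34%, E3, E4: -33%",ring
0309-008,right,agp,3.0,130,60,"E1: -100%",ring
0309-009,left,soc,3.9,130,60,"E4: -100%",directional
0309-009,left,agp,2.8,130,60,"E1: -100%",ring
0309-009,right,soc,1.7,130,60,"E3: -100%",directional
0309-009,right,agp,3.1,130,60,"E1: -100%",ring
0309-010,left,soc,4.6,130,60,"E1: -70%, E2, E3, E4: -10%",ring
0309-010,left,agp,5.1,130,60,"E1: -40%, E2: -60%",directional
0309-010,right,soc,3.8,130,60,"E1: -100%",ring
0309-010,right,agp,3.7,130,60,"E1: -70%, E2, E3, E4: -10%",ring
0309-011,left,soc,5.0,130,60,"E5: -100%",directional
0309-011,left,agp,4.2,130,60,"E2: -75%, E3: -25%",directional
0309-011,right,soc,4.0,130,60,"E4: -100%",directional
0309-011,right,agp,3.6,130,60,"E1: -20%, E2: -28%, E3, E4: -26%",ring
0309-012,left,soc,2.3,130,60,"E5: -34%, E6, E7: -33%",ring
0309-012,left,agp,2.0,130,60,"E1: -30%, E2: -70%",directional
0309-012,right,soc,2.1,130,60,"E5: -34%, E6, E7: -33%",ring
0309-012,right,agp,2.0,130,60,"E2: -70%, E5: -30%",directional
0309-013,left,soc,3.6,130,60,"E6: -100%",directional
0309-013,left,agp,4.5,130,60,"E1: -40%, E2, E3, E4: -20%",ring
0309-013,right,soc,3.7,130,60,"E3: -100%",directional
0309-013,right,agp,5.4,130,60,"E1: -100%",ring
0309-014,left,soc,4.0,130,60,"E2: -34%, E3, E4: -33%",ring
0309-014,left,agp,2.5,130,60,"E1: -70%, E2, E3, E4: -10%",ring
0309-014,right,soc,3.1,130,60,"E2: -100%",directional
0309-014,right,agp,2.0,130,60,"E1: -20%, E2: -80%",directional
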