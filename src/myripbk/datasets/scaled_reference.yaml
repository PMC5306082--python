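# Published whole-liver (scaled) kinetic constants used as the expected
# values for the regeneration report.  Values are stored as the printed
# strings so the comparison can honour each cell's printed precision.
# vmax: umol/h/g liver; k: ml/h/g liver; efficiency: L/h/g liver.
rat:
  DHM: {vmax: "0.924", efficiency: "0.0578"}
  3HM: {vmax: "0.987", efficiency: "0.0119"}
  HM: {vmax: "1.806", efficiency: "0.0177"}
  DHA: {vmax: "2.73", efficiency: "0.0827"}
  HMG: {vmax: "73.788", efficiency: "0.0883"}
  HMO: {vmax: "91.644", efficiency: "0.0155"}
  HMS: {k: "0.15"}
human:
  DHM: {vmax: "0.154", efficiency: "0.0047"}
  3HM: {vmax: "0.557", efficiency: "0.0003"}
  HM: {vmax: "0.326", efficiency: "0.0014"}
  DHA: {vmax: "1.786", efficiency: "0.0151"}
  HMG: {vmax: "0.6864", efficiency: "0.0002"}
  HMO: {vmax: "61.44", efficiency: "0.0189"}
  HMS: {k: "0.14"}
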