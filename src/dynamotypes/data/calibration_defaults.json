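{
 "SN/FLC/hysteresis": {
  "sigma": 0.00501590284788977,
  "cv": 0.0029904068208561193,
  "below_band": true
 },
 "SN/SH/hysteresis": {
  "sigma": 0.006611359225735862,
  "cv": 0.05600346564432177,
  "below_band": false
 },
 "SN/SNIC/hysteresis": {
  "sigma": 0.00037891519631739313,
  "cv": 0.05107159798564026,
  "below_band": true
 },
 "SN/SupH/piecewise": {
  "sigma": 0.05346681766028359,
  "cv": 0.005523761456211147,
  "below_band": true
 },
 "SNIC/FLC/slow_wave": {
  "sigma": 0.10351506289169414,
  "cv": 0.04317284725146708,
  "below_band": true
 },
 "SNIC/SH/piecewise": {
  "sigma": 0.08025444556623632,
  "cv": 0.05265783136063833,
  "below_band": true
 },
 "SNIC/SH/slow_wave": {
  "sigma": 0.035620464019761315,
  "cv": 0.026631856166787746,
  "below_band": true
 },
 "SNIC/SNIC/slow_wave": {
  "sigma": 0.014034292247249624,
  "cv": 0.016611432755100387,
  "below_band": true
 },
 "SNIC/SupH/slow_wave": {
  "sigma": 0.10020577915778049,
  "cv": 0.022166699586978603,
  "below_band": true
 },
 "SubH/FLC/hysteresis": {
  "sigma": 0.005381737057623773,
  "cv": 0.00865593418321409,
  "below_band": true
 },
 "SubH/SH/hysteresis": {
  "sigma": 0.003909907305512825,
  "cv": 0.012217750950333683,
  "below_band": true
 },
 "SubH/SNIC/slow_wave": {
  "sigma": 0.15622125063624073,
  "cv": 0.05361808827633063,
  "below_band": false
 },
 "SubH/SupH/piecewise": {
  "sigma": 0.17315069944517686,
  "cv": 0.050420653773001235,
  "below_band": false
 },
 "SupH/FLC/slow_wave": {
  "sigma": 0.03301979835921065,
  "cv": 0.009558145056861311,
  "below_band": true
 },
 "SupH/SH/piecewise": {
  "sigma": 0.07726921869278325,
  "cv": 0.01594572285024118,
  "below_band": true
 },
 "SupH/SNIC/slow_wave": {
  "sigma": 0.07399325731722478,
  "cv": 0.019908176582005287,
  "below_band": true
 },
 "SupH/SupH/piecewise": {
  "sigma": 0.09188910464015909,
  "cv": 0.06437771669015545,
  "below_band": true
 }
}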