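ctmc

const double k_r1 = 0.184;
const double k_r2 = 0.016;
const double k_r3 = 0.211;

module network
  S : [0..12] init 12;
  E : [0..10] init 10;
  ES : [0..10] init 0;
  P : [0..12] init 0;

  [r1] (E>=1) & (S>=1) & (ES<=9) -> k_r1*E*S : (E'=E-1) & (ES'=ES+1) & (S'=S-1);
  [r2] (ES>=1) & (E<=9) & (S<=11) -> k_r2*ES : (E'=E+1) & (ES'=ES-1) & (S'=S+1);
  [r3] (ES>=1) & (E<=9) & (P<=11) -> k_r3*ES : (E'=E+1) & (ES'=ES-1) & (P'=P+1);
endmodule
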