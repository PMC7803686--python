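[
 {
  "predicted": [
   3.087418,
   3.59506,
   11.008359,
   4.531096,
   2.219409,
   8.408486,
   0.673442,
   10.062493,
   2.970047,
   5.558774
  ],
  "observed": [
   2.842737,
   4.016901,
   9.669429,
   4.502671,
   2.435335,
   8.141774,
   0.811683,
   8.652684,
   2.490357,
   6.02504
  ],
  "r_squared": 0.944091045748378,
  "rmse": 0.6784760824380621,
  "aad_percent": 10.605486237837662
 },
 {
  "predicted": [
   6.412446,
   8.02826,
   8.5019,
   0.753284,
   2.580758,
   7.594006,
   2.476839,
   4.856078,
   4.448082,
   5.233741
  ],
  "observed": [
   7.95089,
   7.83002,
   9.388524,
   1.047481,
   3.091174,
   7.63898,
   2.150513,
   4.779427,
   5.350447,
   4.755452
  ],
  "r_squared": 0.9319029454905143,
  "rmse": 0.6853245347626191,
  "aad_percent": 12.021278049586053
 },
 {
  "predicted": [
   6.204275,
   2.648758,
   8.831566,
   8.042966,
   4.912667
  ],
  "observed": [
   7.371031,
   2.957524,
   8.156967,
   9.649819,
   6.061051
  ],
  "r_squared": 0.772876894188136,
  "rmse": 1.0781931359601586,
  "aad_percent": 14.027551608761751
 },
 {
  "predicted": [
   1.079341,
   7.843719,
   5.486306,
   7.967576,
   9.602383,
   5.943263,
   4.065292,
   0.889436,
   4.049064,
   1.591697,
   6.098558
  ],
  "observed": [
   1.091066,
   9.049823,
   4.873508,
   7.685886,
   9.565236,
   5.008466,
   3.770203,
   0.890786,
   3.82222,
   1.607843,
   6.625334
  ],
  "r_squared": 0.9657965537212495,
  "rmse": 0.5394619793167666,
  "aad_percent": 6.596566954748415
 },
 {
  "predicted": [
   8.92576,
   5.189022,
   3.376115,
   2.167381,
   2.203595,
   4.567299
  ],
  "observed": [
   7.949996,
   5.852989,
   2.734141,
   2.821018,
   2.117088,
   4.564169
  ],
  "r_squared": 0.9111138171675671,
  "rmse": 0.6109872834436357,
  "aad_percent": 12.403785302363314
 }
]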