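range,method,level,tail,median,min,max
1-50,exact,0.95,lower,0.0325,0.0219,0.3679
1-50,prediction,0.95,lower,0.0186,0.0,0.025
1-50,wald,0.95,lower,0.0184,0.0,0.025
>50-100,exact,0.95,lower,0.0287,0.0248,0.0351
>50-100,prediction,0.95,lower,0.0215,0.0172,0.025
>50-100,wald,0.95,lower,0.0216,0.0172,0.0251
>100-500,exact,0.95,lower,0.0267,0.0248,0.0317
>100-500,prediction,0.95,lower,0.0233,0.0194,0.025
>100-500,wald,0.95,lower,0.0233,0.0194,0.0251
>500-1000,exact,0.95,lower,0.0261,0.0249,0.0277
>500-1000,prediction,0.95,lower,0.0239,0.0224,0.025
>500-1000,wald,0.95,lower,0.024,0.0225,0.0251
>1000-10000,exact,0.95,lower,0.0254,0.025,0.0269
>1000-10000,prediction,0.95,lower,0.0246,0.0232,0.025
>1000-10000,wald,0.95,lower,0.0246,0.0232,0.025
1-50,exact,0.95,upper,0.0121,0.0003,0.0177
1-50,prediction,0.95,upper,0.0201,0.0052,0.025
1-50,wald,0.95,upper,0.0301,0.0203,0.084
>50-100,exact,0.95,upper,0.0166,0.0129,0.0196
>50-100,prediction,0.95,upper,0.022,0.0184,0.025
>50-100,wald,0.95,upper,0.028,0.0247,0.0331
>100-500,exact,0.95,upper,0.0203,0.0157,0.0225
>100-500,prediction,0.95,upper,0.0234,0.02,0.025
>100-500,wald,0.95,upper,0.0266,0.0248,0.0307
>500-1000,exact,0.95,upper,0.022,0.0203,0.0232
>500-1000,prediction,0.95,upper,0.024,0.0226,0.025
>500-1000,wald,0.95,upper,0.026,0.0249,0.0275
>1000-10000,exact,0.95,upper,0.0238,0.0216,0.0244
>1000-10000,prediction,0.95,upper,0.0246,0.0233,0.025
>1000-10000,wald,0.95,upper,0.0254,0.0249,0.0268
1-50,exact,0.998,lower,0.0028,0.0016,0.3679
1-50,prediction,0.998,lower,0.0006,0.0,0.001
1-50,wald,0.998,lower,0.0002,0.0,0.0006
>50-100,exact,0.998,lower,0.0018,0.0014,0.0026
>50-100,prediction,0.998,lower,0.0008,0.0006,0.001
>50-100,wald,0.998,lower,0.0005,0.0003,0.0007
>100-500,exact,0.998,lower,0.0013,0.0012,0.002
>100-500,prediction,0.998,lower,0.0009,0.0007,0.001
>100-500,wald,0.998,lower,0.0007,0.0005,0.0009
>500-1000,exact,0.998,lower,0.0012,0.0011,0.0013
>500-1000,prediction,0.998,lower,0.0009,0.0009,0.001
>500-1000,wald,0.998,lower,0.0008,0.0007,0.0009
>1000-10000,exact,0.998,lower,0.0011,0.001,0.0012
>1000-10000,prediction,0.998,lower,0.001,0.0009,0.001
>1000-10000,wald,0.998,lower,0.0009,0.0008,0.001
1-50,exact,0.998,upper,0.0002,0.0,0.0004
1-50,prediction,0.998,upper,0.0007,0.0002,0.001
1-50,wald,0.998,upper,0.0021,0.0014,0.0133
>50-100,exact,0.998,upper,0.0004,0.0002,0.0005
>50-100,prediction,0.998,upper,0.0008,0.0007,0.001
>50-100,wald,0.998,upper,0.0016,0.0013,0.0021
>100-500,exact,0.998,upper,0.0006,0.0004,0.0007
>100-500,prediction,0.998,upper,0.0009,0.0007,0.001
>100-500,wald,0.998,upper,0.0013,0.0011,0.0018
>500-1000,exact,0.998,upper,0.0007,0.0006,0.0008
>500-1000,prediction,0.998,upper,0.0009,0.0009,0.001
>500-1000,wald,0.998,upper,0.0012,0.0011,0.0013
>1000-10000,exact,0.998,upper,0.0009,0.0007,0.0009
>1000-10000,prediction,0.998,upper,0.001,0.0009,0.001
>1000-10000,wald,0.998,upper,0.0011,0.001,0.0012
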