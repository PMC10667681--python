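well,partition,blue_T1,blue_T2,blue_T3,blue_T4,green_T1,green_T2,green_T3,green_T4,yellow_T1,yellow_T2,yellow_T3,yellow_T4,red_T1,red_T2,red_T3,red_T4
EX01,0,2161.254,3144.693,3142.135,3149.562,3058.94,3045.112,3040.31,3026.967,3005.402,3023.411,3029.965,3057.571,3181.941,3195.494,3171.931,3161.03
EX01,1,2127.352,2995.866,3039.254,2994.899,3217.975,3190.072,3219.466,3210.708,3099.915,3101.713,3092.188,3109.264,2963.23,2951.786,2951.009,2972.549
EX01,2,2197.395,3087.974,3084.176,3090.417,3141.469,3124.512,3114.676,3138.353,3145.38,3162.752,3141.526,3119.435,3008.939,3054.673,3055.775,3026.945
EX01,3,2144.266,3062.811,3024.253,3027.482,3157.111,3140.78,3146.908,3144.417,3112.425,3129.047,3108.587,3117.184,2909.161,2938.576,2926.899,2921.38
EX01,4,2108.013,2998.483,3017.748,2984.069,3101.254,3093.273,3095.699,3116.326,3080.648,3092.927,3070.008,3061.691,3021.889,3028.943,3027.946,3008.873
EX01,5,2088.948,3080.334,3116.107,3106.249,2997.036,3005.551,2987.852,3000.987,3093.64,3107.389,3077.506,3078.663,3135.188,3166.636,3152.379,3160.824
EX01,6,2158.398,3066.844,3041.818,3046.278,3261.92,3206.782,3209.859,3257.202,3126.503,3063.687,3076.065,3087.002,2990.977,2950.715,2961.71,2976.872
EX01,7,2071.973,3040.834,3045.067,3026.159,3103.103,3102.665,3110.41,3098.177,3374.187,3383.295,3368.866,3372.171,2958.092,2957.308,2946.637,2961.986
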