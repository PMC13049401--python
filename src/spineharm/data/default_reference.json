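{"n_levels": 256, "hist": [0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 4.1520514455782306e-07, 0.0, 4.567256590136054e-06, 9.964923469387754e-06, 2.491230867346939e-05, 6.352638711734694e-05, 0.00015362590348639457, 0.00029355003720238094, 0.0005073806866496599, 0.0007685447225765306, 0.0011663112510629252, 0.001612656781462585, 0.0021275111607142855, 0.0026523304634353743, 0.0032871791294642855, 0.0038236241762329933, 0.004484630766369048, 0.005176777742346939, 0.005992655851403061, 0.006789434523809524, 0.007639359454719388, 0.008513366284013606, 0.009336302880527211, 0.010552023543792517, 0.01191348121279762, 0.01325791547087585, 0.01453757772640306, 0.015484660661139456, 0.01587453829187925, 0.016180544483418366, 0.01604477240114796, 0.015818485597363947, 0.015788590826955783, 0.015853362829506803, 0.015860006111819726, 0.01577405864689626, 0.015761187287414966, 0.01570887143920068, 0.015571023331207483, 0.0155984268707483, 0.015560643202593538, 0.015579742639243197, 0.01556770169005102, 0.015763678518282313, 0.015719666772959183, 0.01593972549957483, 0.01596422260310374, 0.01593972549957483, 0.015565625664328231, 0.015677731053358842, 0.015584725100977892, 0.015691017617984693, 0.015533239663052721, 0.015640777795493197, 0.015585970716411565, 0.015790666852678572, 0.015851702008928572, 0.016004082296981293, 0.016209608843537414, 0.016134456712372448, 0.016276456871811226, 0.016222480203018707, 0.016071760735544217, 0.016165597098214284, 0.015987889296343538, 0.015796064519557822, 0.01551040338010204, 0.015245917703018707, 0.01490960153592687, 0.014691203629889456, 0.014227419483418368, 0.013560600021258503, 0.013172798416241497, 0.01260728900935374, 0.011870299877763606, 0.01140983737244898, 0.010601432955994899, 0.009985268521471089, 0.009167314386692178, 0.00826839524872449, 0.007399370881164966, 0.006368001302083333, 0.0053457662361819725, 0.0041495602147108845, 0.003075839710884354, 0.002053189439838435, 0.001380141900510204, 0.0009026559842687075, 0.0006269597682823129, 0.0005289713541666666, 0.000481222762542517, 0.0004509127869897959, 0.0004376262223639456, 0.0004181115805697279, 0.00043347417091836734, 0.00042517006802721087, 0.0004376262223639456, 0.0004309829400510204, 0.00043887183779761906, 0.0004338893760629252, 0.000445930325255102, 0.0004239244525935374, 0.0003898776307397959, 0.00036662614264455784, 0.000347526705994898, 0.0003645501169217687, 0.000406070631377551, 0.00037409983524659863, 0.00043513499149659863, 0.0004442695046768707, 0.00047665550595238094, 0.00048620522427721087, 0.0005156847895408163, 0.0005464099702380952, 0.0005601117400085034, 0.0005646789965986394, 0.0005949889721513606, 0.0006074451264880952, 0.0006236381271258504, 0.0005879304846938776, 0.0006024626647534013, 0.0005364450467687075, 0.000516515199829932, 0.000499906994047619, 0.00046336894132653064, 0.000420187606292517, 0.00042724609375, 0.00041146829825680273, 0.00039610570790816324, 0.0003965209130527211, 0.00042267883715986395, 0.0005036438403486394, 0.0005327082004676871, 0.0006427375637755102, 0.0006601761798469387, 0.0007552581579506803, 0.0008764980601615646, 0.0010317847842261905, 0.0012846447172619048, 0.001573212292729592, 0.001819428943452381, 0.002161973187712585, 0.0023907512223639454, 0.002429780505952381, 0.0024501255580357145, 0.002378295068027211, 0.0023189207323554423, 0.0022761546024659862, 0.0022429381909013606, 0.0020552654655612247, 0.0020174817974064627, 0.0019244758450255102, 0.0018119552508503401, 0.0016790896045918368, 0.0014640133397108843, 0.0011355860703656463, 0.0007909658003826531, 0.00045506483843537417, 0.00024870788159013605, 0.0001058773118622449, 3.487723214285714e-05, 1.0795333758503401e-05, 1.6608205782312922e-06, 8.304102891156461e-07, 4.1520514455782306e-07, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0], "brightness": 76.41636461627726, "spread": 0.10668611576438099, "n_pixels": 2408448, "profile_id": "default-reference-v1"}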